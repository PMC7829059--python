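"""Stratified aggregation: conservation, outliers, cycle profiles, counts I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overlaperr.illumina import FlowcellLayout, ReadLocation
from overlaperr.overlap import PairOverlap
from overlaperr.rates import (DEFAULT_MIN_BASES, ErrorTally, RateEstimate,
                              RunTallies, classify_outliers, cycle_profile,
                              merge_counts, rate, read_counts, surface_compare,
                              write_counts)


def loc(tile=1101, lane=1, flowcell="FC1", instrument="I1"):
    return ReadLocation(instrument, 1, flowcell, lane, tile, 0, 0)


def overlap(n_r, m_r, tile=1101, lane=1, flowcell="FC1", instrument="I1",
            fwd_start=6, rev_start=6):
    """Synthetic PairOverlap with contiguous cycle runs starting at a cycle."""
    fwd_cycles = np.arange(fwd_start, fwd_start + n_r, dtype=np.int64)
    rev_cycles = np.arange(rev_start + n_r - 1, rev_start - 1, -1, dtype=np.int64)
    disc = np.zeros(n_r, dtype=bool)
    disc[:m_r] = True
    return PairOverlap(n_r=n_r, m_r=m_r, fwd_cycles=fwd_cycles,
                       rev_cycles=rev_cycles, discordant=disc,
                       location=loc(tile, lane, flowcell, instrument),
                       ref_name="ref1")


class TestRate:
    def test_arithmetic(self):
        est = rate(ErrorTally("t", 10, 1_000_000, 5), min_bases=0)
        assert est.rate_pm == pytest.approx(10.0)

    def test_zero_numerator_sufficient(self):
        est = rate(ErrorTally("t", 0, 2_000_000, 5), min_bases=2_000_000)
        assert est.rate_pm == 0.0 and est.sufficient

    def test_insufficient_below_gate(self):
        est = rate(ErrorTally("t", 5, 1_500_000, 5), min_bases=2_000_000)
        assert est.rate_pm == pytest.approx(3.3333333)
        assert not est.sufficient

    def test_zero_bases_undefined_not_zero(self):
        est = rate(ErrorTally("t", 0, 0, 0), min_bases=1)
        assert math.isnan(est.rate_pm) and not est.defined


class TestAccumulate:
    def test_single_pair_tile_bookkeeping(self):
        tal = RunTallies()
        tal.accumulate(overlap(100, 2))
        t = tal.tiles[("FC1", 1, 1101)]
        assert (t.mismatches, t.bases, t.pairs) == (2, 200, 1)

    def test_surface_routing_and_flowcell_union(self):
        tal = RunTallies()
        tal.accumulate(overlap(50, 1, tile=1101))
        tal.accumulate(overlap(60, 0, tile=2101))
        assert tal.surfaces[("FC1", 1)].bases == 100
        assert tal.surfaces[("FC1", 2)].bases == 120
        assert tal.flowcells["FC1"].bases == 220
        assert tal.flowcells["FC1"].mismatches == 1

    def test_empty_overlap_counts_pair_only(self):
        tal = RunTallies()
        tal.accumulate(overlap(0, 0))
        t = tal.tiles[("FC1", 1, 1101)]
        assert (t.mismatches, t.bases, t.pairs) == (0, 0, 1)

    def test_cycle_tallies_one_base_per_mate_per_position(self):
        tal = RunTallies()
        tal.accumulate(overlap(10, 1, fwd_start=6, rev_start=3))
        prof = cycle_profile(tal)
        fwd = prof[prof.mate == "fwd"].set_index("cycle")
        rev = prof[prof.mate == "rev"].set_index("cycle")
        assert fwd.loc[6:15, "bases"].tolist() == [1] * 10
        assert rev.loc[3:12, "bases"].tolist() == [1] * 10
        # one discordance charges both mates' cycles
        assert fwd["mismatches"].sum() == 1
        assert rev["mismatches"].sum() == 1

    def test_conservation_exact(self):
        rng = np.random.default_rng(3)
        tal = RunTallies()
        for _ in range(200):
            tile = int(rng.choice([1101, 1102, 2101, 2102]))
            n = int(rng.integers(0, 90))
            m = int(rng.integers(0, max(n // 10, 1))) if n else 0
            tal.accumulate(overlap(n, m, tile=tile,
                                   lane=int(rng.integers(1, 3))))
        tal.assert_conservation()
        tile_b = sum(t.bases for t in tal.tiles.values())
        assert tile_b == tal.flowcells["FC1"].bases


class TestClassifyOutliers:
    def make(self, rate_pm, bases=10_000_000, sufficient=True):
        mism = int(rate_pm * bases / 1e6)
        return RateEstimate("t", mism, bases, rate_pm, sufficient)

    def test_partition(self):
        part = classify_outliers([
            self.make(150.0), self.make(99.0),
            self.make(500.0, bases=10_000, sufficient=False)])
        assert [e.rate_pm for e in part.outlier] == [150.0]
        assert [e.rate_pm for e in part.normal] == [99.0]
        assert [e.rate_pm for e in part.insufficient] == [500.0]

    def test_threshold_is_strict(self):
        part = classify_outliers([self.make(100.0)])
        assert part.normal and not part.outlier


class TestSurfaceCompare:
    def test_outlier_fraction_per_surface(self):
        tal = RunTallies(layout=FlowcellLayout(swaths_per_lane=1,
                                               tiles_per_swath=10))
        for pos in range(1, 11):
            for _ in range(20):
                tal.accumulate(overlap(90, 0, tile=1100 + pos))
                hot = 500 if pos == 1 else 0
                tal.accumulate(overlap(90, hot and 9, tile=2100 + pos))
        df = surface_compare(tal, tile_min_bases=1000, surface_min_bases=1000)
        top = df[df.surface == 1].iloc[0]
        bot = df[df.surface == 2].iloc[0]
        assert top.outlier_tile_fraction == 0.0
        assert bot.outlier_tile_fraction == pytest.approx(0.1)
        assert not top.flagged and not bot.flagged  # 10% is not > 10%

    def test_symmetric_surfaces_equal_rates(self):
        tal = RunTallies()
        tal.accumulate(overlap(50, 1, tile=1101))
        tal.accumulate(overlap(50, 1, tile=2101))
        df = surface_compare(tal, tile_min_bases=1, surface_min_bases=1)
        assert df[df.surface == 1].rate_pm.iloc[0] == \
            df[df.surface == 2].rate_pm.iloc[0]

    def test_bottom_elevated_flowcell_detected(self):
        """Binomial simulation: with the bottom surface at 3x the top's true
        rate and 1e7 bases per surface, the bottom estimate exceeds the top
        in >= 99% of replicates."""
        rng = np.random.default_rng(17)
        p_top, bases = 10e-6, 10_000_000
        wins = 0
        n_rep = 300
        for _ in range(n_rep):
            top = rate(ErrorTally("t", int(rng.binomial(bases, p_top)), bases, 1),
                       min_bases=1_000_000)
            bot = rate(ErrorTally("b", int(rng.binomial(bases, 3 * p_top)), bases, 1),
                       min_bases=1_000_000)
            wins += bot.rate_pm > top.rate_pm
        assert wins / n_rep >= 0.99


class TestCycleProfile:
    def test_trimmed_cycles_flagged_not_zero(self):
        tal = RunTallies()
        for _ in range(10):
            tal.accumulate(overlap(20, 0, fwd_start=6, rev_start=6))
        prof = cycle_profile(tal)
        head = prof[(prof.mate == "fwd") & (prof.cycle <= 5)]
        assert (head.bases == 0).all()
        assert not head.defined.any()
        assert head.rate_pm.isna().all()

    def test_planted_hot_cycle_recovered(self):
        """A cycle with a strongly elevated error rate stands out from the
        median profile by more than 10x."""
        rng = np.random.default_rng(23)
        tal = RunTallies()
        hot_cycle = 42
        p_base, p_hot = 10e-6, 10e-3
        for _ in range(3000):
            n = 60
            fwd_cycles = np.arange(6, 6 + n, dtype=np.int64)
            rev_cycles = np.arange(6 + n - 1, 5, -1, dtype=np.int64)
            p = np.where(fwd_cycles == hot_cycle, p_hot, p_base)
            disc = rng.random(n) < p
            tal.accumulate(PairOverlap(n, int(disc.sum()), fwd_cycles,
                                       rev_cycles, disc, location=loc(),
                                       ref_name="ref1"))
        prof = cycle_profile(tal)
        fwd = prof[(prof.mate == "fwd") & prof.defined].set_index("cycle")
        hot = fwd.loc[hot_cycle, "rate_pm"]
        median = fwd["rate_pm"].median()
        assert hot > 10 * max(median, 1.0)


class TestMergeAndIO:
    def build(self, seed=0):
        rng = np.random.default_rng(seed)
        tal = RunTallies()
        for _ in range(100):
            tal.accumulate(overlap(int(rng.integers(1, 90)),
                                   int(rng.integers(0, 3)),
                                   tile=int(rng.choice([1101, 2101])),
                                   flowcell=str(rng.choice(["FCA", "FCB"]))))
        return tal

    def test_counts_roundtrip(self, tmp_path):
        tal = self.build()
        path = tmp_path / "counts.tsv"
        write_counts(tal, path)
        back = read_counts(path)
        assert back.flowcells.keys() == tal.flowcells.keys()
        for fc in tal.flowcells:
            assert back.flowcells[fc].bases == tal.flowcells[fc].bases
            assert back.flowcells[fc].mismatches == tal.flowcells[fc].mismatches
        assert back.tiles == tal.tiles or all(
            back.tiles[k].bases == tal.tiles[k].bases for k in tal.tiles)
        back.assert_conservation()

    def test_merge_equals_pooled_counts(self, tmp_path):
        a, b = self.build(1), self.build(2)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_counts(a, pa)
        write_counts(b, pb)
        merged = merge_counts([pa, pb])
        for fc in set(a.flowcells) | set(b.flowcells):
            want = (a.flowcells.get(fc, ErrorTally(fc)).bases
                    + b.flowcells.get(fc, ErrorTally(fc)).bases)
            assert merged.flowcells[fc].bases == want
        merged.assert_conservation()

    def test_sequencer_view_pools_counts_not_rates(self):
        tal = RunTallies()
        tal.accumulate(overlap(100, 1, flowcell="FCA", instrument="I1"))
        tal.accumulate(overlap(100, 3, flowcell="FCB", instrument="I1"))
        est = tal.sequencer_estimates(min_bases=1)["I1"]
        # pooled-count rate, not the mean of the two flow-cell rates
        assert est.rate_pm == pytest.approx(4 / 400 * 1e6)


@given(st.lists(
    st.tuples(st.integers(0, 50), st.integers(100, 100000)), min_size=2,
    max_size=8))
@settings(max_examples=100, derandomize=True)
def test_removing_above_average_stratum_never_raises_aggregate(counts):
    """Weighted-mean property: dropping a stratum whose rate exceeds the
    aggregate cannot increase the aggregate rate."""
    counts = [(min(m, b), b) for m, b in counts]
    tot_m = sum(m for m, _ in counts)
    tot_b = sum(b for _, b in counts)
    agg = tot_m / tot_b
    for m, b in counts:
        if m / b > agg:
            rest_m, rest_b = tot_m - m, tot_b - b
            if rest_b:
                assert rest_m / rest_b <= agg + 1e-15
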