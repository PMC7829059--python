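"""Deep-pileup genotyping, site-specific error rates and run comparison."""

import math

import numpy as np
import pytest

from conftest import make_pair, make_read, write_sam
from overlaperr.filters import FilterConfig
from overlaperr.pileup import (SiteCounts, _make_site, compare_runs, oer,
                               pileup, read_sites, site_oer_records,
                               substitution_class, write_sites)
from overlaperr.simulate import SimConfig, Spikein, simulate_run, simulated_reference
from overlaperr.suppress import TileSet


def site(counts, ref="C", min_depth=10, min_frac=0.95, pos=100):
    arr = np.array(counts, dtype=np.int64)
    return _make_site("ref1", pos, ref, arr, min_depth, min_frac)


class TestGenotyping:
    def test_unanimous_site_callable(self):
        s = site([20, 0, 0, 0])
        assert s.callable and s.dominant == "A" and s.depth == 20

    @pytest.mark.parametrize("depth,callable_", [(10, False), (11, True)])
    def test_depth_boundary_strictly_greater_than_ten(self, depth, callable_):
        s = site([depth, 0, 0, 0])
        assert s.callable is callable_

    @pytest.mark.parametrize("n_alt,callable_", [(6, False), (4, True)])
    def test_dominant_fraction_boundary(self, n_alt, callable_):
        # 94/100 = 0.94 fails the > 0.95 rule; 96/100 passes
        s = site([100 - n_alt, n_alt, 0, 0])
        assert s.callable is callable_
        assert s.dominant_fraction == pytest.approx((100 - n_alt) / 100)


class TestOER:
    def test_rate_arithmetic(self):
        s = site([999_997, 3, 0, 0])
        rec = oer(s, "C")
        assert rec.rate == pytest.approx(3e-6)
        assert rec.substitution == "A>C"
        assert rec.paired_type == "A>C/T>G"

    def test_zero_numerator(self):
        s = site([100, 0, 0, 0])
        assert oer(s, "C").rate == 0.0

    def test_uncallable_site_refused(self):
        s = site([10, 0, 0, 0])
        with pytest.raises(ValueError):
            oer(s, "C")

    def test_dominant_allele_refused_as_mismatch(self):
        s = site([100, 0, 0, 0])
        with pytest.raises(ValueError):
            oer(s, "A")

    def test_rates_plus_dominant_fraction_sum_to_one(self):
        s = site([960, 20, 15, 5])
        total = sum(r.rate for r in site_oer_records(s)) + s.dominant_fraction
        assert total == pytest.approx(1.0)

    @pytest.mark.parametrize("g,m,label", [
        ("A", "C", "A>C/T>G"), ("T", "G", "A>C/T>G"),
        ("C", "G", "C>G/G>C"), ("G", "C", "C>G/G>C"),
        ("T", "A", "A>T/T>A"), ("G", "A", "C>T/G>A")])
    def test_complementary_pairing(self, g, m, label):
        assert substitution_class(g, m) == label


class TestPileup:
    def test_counts_respect_filters(self, tmp_path):
        # mapq 54 read contributes nothing; low-quality base skipped
        good, good_r = make_pair(fwd_start=100, rev_start=130)
        quals = [37] * 100
        quals[10] = 10
        lowq = make_read(name="M:0:F:1:1101:5:0", start=100, quals=quals)
        bad = make_read(name="M:0:F:1:1101:6:0", start=100, mapq=54)
        path = write_sam(tmp_path / "p.sam", [good, good_r, lowq, bad])
        ref = tmp_path / "ref.fa"
        ref.write_text(">ref1\n" + "A" * 400 + "\n")
        sites = pileup(path, ref, regions=[("ref1", 100, 300)])
        # pos 111 (1-based): good fwd + lowq's bad base excluded
        assert sites[("ref1", 111)].depth == 1
        # pos 120: good fwd + lowq both count (cycles 21, beyond trim)
        assert sites[("ref1", 121)].depth == 2

    def test_excluded_tiles_skipped_entirely(self, tmp_path):
        a, ar = make_pair(name="M:0:F:1:1101:0:0", fwd_start=100, rev_start=130)
        b, br = make_pair(name="M:0:F:1:2159:1:0", fwd_start=100, rev_start=130)
        path = write_sam(tmp_path / "p.sam", [a, ar, b, br])
        ref = tmp_path / "ref.fa"
        ref.write_text(">ref1\n" + "A" * 400 + "\n")
        excl = TileSet(tiles={("F", 2159)})
        sites = pileup(path, ref, excluded_tiles=excl)
        peak = max(s.depth for s in sites.values())
        assert peak == 2  # only the tile-1101 pair remains

    def test_region_outside_reference_errors(self, tmp_path):
        ref = tmp_path / "ref.fa"
        ref.write_text(">ref1\n" + "A" * 100 + "\n")
        path = write_sam(tmp_path / "p.sam", [])
        with pytest.raises(ValueError):
            pileup(path, ref, regions=[("ref1", 0, 500)])
        with pytest.raises(ValueError):
            pileup(path, ref, regions=[("refX", 0, 10)])

    def test_n_never_counted(self, tmp_path):
        seq = "A" * 50 + "N" + "A" * 49
        rec = make_read(seq=seq, start=100)
        path = write_sam(tmp_path / "p.sam", [rec])
        ref = tmp_path / "ref.fa"
        ref.write_text(">ref1\n" + "A" * 400 + "\n")
        sites = pileup(path, ref)
        assert ("ref1", 151) not in sites  # the N position has zero depth


class TestCompareRuns:
    def sites_from(self, spec):
        return {("ref1", pos): site(c, pos=pos) for pos, c in spec.items()}

    def test_identity_comparison(self):
        a = self.sites_from({100: [960, 20, 15, 5], 200: [0, 990, 5, 5]})
        res = compare_runs(a, a)
        assert (res.sites.fold_change == 1.0).all()
        seen = res.summary.dropna(subset=["p_value"])
        assert np.allclose(seen.p_value, 1.0)
        assert (seen.frac_fold_gt2 == 0.0).all()

    def test_halved_rate_gives_fold_two(self):
        a = self.sites_from({100: [980, 20, 0, 0]})
        b = self.sites_from({100: [990, 10, 0, 0]})
        res = compare_runs(a, b)
        row = res.sites[res.sites.substitution == "A>C"].iloc[0]
        assert row.fold_change == pytest.approx(2.0)

    def test_zero_after_suppression_reported_as_bound(self):
        a = self.sites_from({100: [980, 20, 0, 0]})
        b = self.sites_from({100: [1000, 0, 0, 0]})
        res = compare_runs(a, b)
        row = res.sites[res.sites.substitution == "A>C"].iloc[0]
        assert row.fold_is_bound
        assert row.fold_change == pytest.approx((20 / 1000) / (0.5 / 1000))

    def test_disjoint_sites_error(self):
        a = self.sites_from({100: [100, 0, 0, 0]})
        b = self.sites_from({200: [100, 0, 0, 0]})
        with pytest.raises(ValueError):
            compare_runs(a, b)

    def test_spikeins_reported_separately(self):
        a = self.sites_from({100: [980, 20, 0, 0], 300: [900, 100, 0, 0]})
        b = self.sites_from({100: [980, 20, 0, 0], 300: [890, 110, 0, 0]})
        res = compare_runs(a, b, spikeins=[("ref1", 300, "A", "C")])
        assert len(res.spikeins) == 1
        assert res.spikeins.iloc[0].af_a == pytest.approx(0.1)
        # the spike-in site never enters the error summaries
        assert set(res.sites.pos) == {100}

    def test_sites_tsv_roundtrip(self, tmp_path):
        a = self.sites_from({100: [960, 20, 15, 5], 200: [5, 990, 0, 5]})
        path = tmp_path / "sites.tsv"
        write_sites(a, path)
        back = read_sites(path)
        assert back.keys() == a.keys()
        for k in a:
            assert back[k].counts == a[k].counts
            assert back[k].callable == a[k].callable


class TestSuppressionEffectOnOER:
    def test_tile_concentrated_errors_shrink_after_exclusion(self, tmp_path):
        """Errors planted on one tile raise oER there; excluding the tile
        lowers the affected sites' error rates while a spike-in variant's
        allele fraction moves by less than 3 binomial SDs."""
        af = 0.01
        cfg = SimConfig(reference_length=300, pairs_per_tile=2500,
                        tile_error_rates={1101: 0.0, 2101: 2e-3}, seed=21)
        ref = simulated_reference(cfg)
        pos = 150
        alt = "A" if ref[pos - 1] != "A" else "C"
        cfg.spikeins = [Spikein(pos, alt, af)]
        out = simulate_run(cfg, tmp_path)
        before = pileup(out.sam, out.reference)
        excl = TileSet(tiles={(cfg.flowcell, 2101)})
        after = pileup(out.sam, out.reference, excluded_tiles=excl)
        res = compare_runs(before, after,
                           spikeins=[(cfg.ref_name, pos, ref[pos - 1], alt)])
        classes = res.summary.dropna(subset=["median_a"])
        assert (classes.median_a >= classes.median_b).all()
        hot = out.truth_events[out.truth_events.kind.str.startswith("sequencer")]
        hot_sites = set(hot.pos)
        mean_before = np.mean([1 - before[(cfg.ref_name, p)].dominant_fraction
                               for p in hot_sites])
        mean_after = np.mean([1 - after[(cfg.ref_name, p)].dominant_fraction
                              for p in hot_sites])
        assert mean_before > mean_after
        spike = res.spikeins.iloc[0]
        assert abs(spike.delta) < 3 * spike.binomial_sd
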