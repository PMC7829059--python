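"""Stratified error-rate aggregation.

Counts are the interchange currency: every stratum keeps integer
``(mismatches, bases, pairs)`` tallies and rates are always derived as
``mismatches / bases * 1e6`` (per-million, "pm") downstream, so merging
tallies across runs or flow cells is exact.  The stratum hierarchy follows
the physical nesting of an Illumina run — tile within swath within lane
within surface within flow cell — plus per-cycle tallies for each mate.

Sufficiency gates keep noise out of summaries: a stratum with too few
sequenced bases is flagged insufficient and excluded from outlier
statistics rather than reported as a (meaningless) rate.  The defaults are
2,000,000 bases at flow-cell level and 1,000,000 at surface level; the
count is of sequenced bases (``sum 2*n_r``; set ``min_bases_unit`` to
``"positions"`` to gate on ``sum n_r`` instead).  A stratum whose rate
exceeds 100 pm is an outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .illumina import FlowcellLayout, LayoutError, decode_tile
from .overlap import PairOverlap

__all__ = [
    "ErrorTally",
    "RateEstimate",
    "OutlierPartition",
    "RunTallies",
    "rate",
    "classify_outliers",
    "surface_compare",
    "cycle_profile",
    "write_counts",
    "read_counts",
    "merge_counts",
    "DEFAULT_MIN_BASES",
    "OUTLIER_THRESHOLD_PM",
]

OUTLIER_THRESHOLD_PM = 100.0

DEFAULT_MIN_BASES = {
    "flowcell": 2_000_000,
    "lane": 2_000_000,
    "surface": 1_000_000,
    "tile": 100_000,
    "cycle": 1,
}

_LEVELS = ("tile", "lane", "surface", "flowcell", "cycle")


@dataclass(slots=True)
class ErrorTally:
    """Additive (mismatches, bases, pairs) counter for one stratum."""

    key: object
    mismatches: int = 0
    bases: int = 0
    pairs: int = 0

    def add(self, mismatches: int, bases: int, pairs: int = 0) -> None:
        self.mismatches += mismatches
        self.bases += bases
        self.pairs += pairs

    def __add__(self, other: "ErrorTally") -> "ErrorTally":
        if self.key != other.key:
            raise ValueError(f"cannot add tallies for {self.key!r} and {other.key!r}")
        return ErrorTally(self.key, self.mismatches + other.mismatches,
                          self.bases + other.bases, self.pairs + other.pairs)


@dataclass(frozen=True, slots=True)
class RateEstimate:
    """An error rate in events per million with its underlying counts.

    ``rate_pm`` is NaN when ``bases == 0`` (undefined, never reported as 0);
    ``sufficient`` says whether the stratum met its minimum base count.
    """

    stratum: object
    mismatches: int
    bases: int
    rate_pm: float
    sufficient: bool

    @property
    def defined(self) -> bool:
        return self.bases > 0


def rate(tally: ErrorTally, min_bases: int) -> RateEstimate:
    """Turn a finalized tally into a :class:`RateEstimate`."""
    if tally.bases == 0:
        return RateEstimate(tally.key, tally.mismatches, 0, nan, False)
    return RateEstimate(
        stratum=tally.key,
        mismatches=tally.mismatches,
        bases=tally.bases,
        rate_pm=tally.mismatches / tally.bases * 1e6,
        sufficient=tally.bases >= min_bases,
    )


@dataclass
class OutlierPartition:
    outlier: list[RateEstimate] = field(default_factory=list)
    normal: list[RateEstimate] = field(default_factory=list)
    insufficient: list[RateEstimate] = field(default_factory=list)

    @property
    def outlier_keys(self) -> list:
        return [e.stratum for e in self.outlier]


def classify_outliers(estimates: Iterable[RateEstimate],
                      threshold_pm: float = OUTLIER_THRESHOLD_PM) -> OutlierPartition:
    """Partition strata into outlier (> threshold), normal, insufficient.

    Insufficient estimates are never classified either way: a stratum that
    did not reach its minimum base count carries no evidence.
    """
    part = OutlierPartition()
    for est in estimates:
        if not est.sufficient:
            part.insufficient.append(est)
        elif est.rate_pm > threshold_pm:
            part.outlier.append(est)
        else:
            part.normal.append(est)
    return part


class RunTallies:
    """Nested stratum tallies for one or more sequencing runs.

    ``accumulate`` routes each :class:`~overlaperr.overlap.PairOverlap` into
    the tile, lane, surface and flow-cell strata of its origin (surfaces
    are decoded from the tile number) and into the per-cycle tallies of
    each mate.  Tile keys are ``(flowcell, lane, tile)``; cycle keys are
    ``(mate, cycle)`` with mate in {"fwd", "rev"}.
    """

    def __init__(self, layout: FlowcellLayout | None = None,
                 min_bases_unit: str = "bases"):
        if min_bases_unit not in ("bases", "positions"):
            raise ValueError("min_bases_unit must be 'bases' or 'positions'")
        self.layout = layout
        self.min_bases_unit = min_bases_unit
        self.tiles: dict[tuple, ErrorTally] = {}
        self.lanes: dict[tuple, ErrorTally] = {}
        self.surfaces: dict[tuple, ErrorTally] = {}
        self.flowcells: dict[str, ErrorTally] = {}
        self.instruments: dict[str, str] = {}  # flowcell -> instrument id
        self._surface_cache: dict[int, int] = {}
        self._cycle_mism = {"fwd": np.zeros(0, np.int64), "rev": np.zeros(0, np.int64)}
        self._cycle_bases = {"fwd": np.zeros(0, np.int64), "rev": np.zeros(0, np.int64)}
        self._cycle_pairs = {"fwd": np.zeros(0, np.int64), "rev": np.zeros(0, np.int64)}

    # ------------------------------------------------------------------ build

    def _surface_of(self, tile: int) -> int:
        surf = self._surface_cache.get(tile)
        if surf is None:
            layout = self.layout
            if layout is None:
                # infer a digit scheme from the tile's digit count
                scheme = "SWCPP" if len(str(tile)) == 5 else "SWPP"
                layout = FlowcellLayout(swaths_per_lane=9, tiles_per_swath=99,
                                        tile_digit_scheme=scheme)
            try:
                surf = decode_tile(tile, layout).surface
            except LayoutError:
                surf = 0  # undecodable: tallied under surface 0, never dropped
            self._surface_cache[tile] = surf
        return surf

    def _bump(self, table: dict, key, m: int, b: int) -> None:
        tally = table.get(key)
        if tally is None:
            tally = table[key] = ErrorTally(key)
        tally.mismatches += m
        tally.bases += b
        tally.pairs += 1

    def _ensure_cycles(self, n: int) -> None:
        if len(self._cycle_bases["fwd"]) < n:
            for table in (self._cycle_mism, self._cycle_bases, self._cycle_pairs):
                for mate in ("fwd", "rev"):
                    old = table[mate]
                    grown = np.zeros(max(n, 2 * len(old)), np.int64)
                    grown[: len(old)] = old
                    table[mate] = grown

    def accumulate(self, ov: PairOverlap) -> None:
        """Add one pair's overlap tally to every stratum it belongs to."""
        loc = ov.location
        if loc is None:
            raise ValueError("PairOverlap without a parsed ReadLocation")
        m, b = ov.m_r, 2 * ov.n_r
        fc = loc.flowcell
        self._bump(self.tiles, (fc, loc.lane, loc.tile), m, b)
        self._bump(self.lanes, (fc, loc.lane), m, b)
        self._bump(self.surfaces, (fc, self._surface_of(loc.tile)), m, b)
        self._bump(self.flowcells, fc, m, b)
        self.instruments.setdefault(fc, loc.instrument)
        if ov.n_r == 0:
            return
        for mate, cycles in (("fwd", ov.fwd_cycles), ("rev", ov.rev_cycles)):
            cmin = int(cycles.min())
            cmax = int(cycles.max())
            self._ensure_cycles(cmax)
            bases = self._cycle_bases[mate]
            pairs = self._cycle_pairs[mate]
            if cmax - cmin + 1 == len(cycles):  # contiguous cycle run (common)
                bases[cmin - 1: cmax] += 1
                pairs[cmin - 1: cmax] += 1
            else:
                np.add.at(bases, cycles - 1, 1)
                np.add.at(pairs, cycles - 1, 1)
            if ov.m_r:
                mism = self._cycle_mism[mate]
                for c in cycles[ov.discordant]:
                    mism[c - 1] += 1

    def extend(self, overlaps: Iterable[PairOverlap]) -> "RunTallies":
        for ov in overlaps:
            self.accumulate(ov)
        return self

    # ------------------------------------------------------------------ query

    def _table(self, level: str) -> Mapping:
        if level == "cycle":
            out = {}
            for mate in ("fwd", "rev"):
                bases = self._cycle_bases[mate]
                for c in range(len(bases)):
                    key = (mate, c + 1)
                    out[key] = ErrorTally(key, int(self._cycle_mism[mate][c]),
                                          int(bases[c]), int(self._cycle_pairs[mate][c]))
            return out
        return {"tile": self.tiles, "lane": self.lanes, "surface": self.surfaces,
                "flowcell": self.flowcells}[level]

    def cycle_count(self) -> int:
        return len(self._cycle_bases["fwd"])

    def _gate_bases(self, min_bases: int) -> int:
        # sufficiency thresholds are stated in "overlapping base pairs";
        # with unit "positions" they gate sum(n_r) == bases / 2
        return 2 * min_bases if self.min_bases_unit == "positions" else min_bases

    def estimates(self, level: str, min_bases: int | None = None) -> dict:
        """Per-stratum :class:`RateEstimate` dict for one hierarchy level."""
        if level not in _LEVELS:
            raise ValueError(f"unknown level {level!r}; expected one of {_LEVELS}")
        if min_bases is None:
            min_bases = DEFAULT_MIN_BASES[level]
        gate = self._gate_bases(min_bases)
        return {key: rate(t, gate) for key, t in sorted(self._table(level).items())}

    def sequencer_estimates(self, min_bases: int | None = None) -> dict:
        """Pooled per-instrument rates (union of each instrument's flow cells)."""
        if min_bases is None:
            min_bases = DEFAULT_MIN_BASES["flowcell"]
        pooled: dict[str, ErrorTally] = {}
        for fc, tally in sorted(self.flowcells.items()):
            instrument = self.instruments.get(fc, "?")
            agg = pooled.setdefault(instrument, ErrorTally(instrument))
            agg.add(tally.mismatches, tally.bases, tally.pairs)
        gate = self._gate_bases(min_bases)
        return {key: rate(t, gate) for key, t in pooled.items()}

    def totals(self) -> ErrorTally:
        out = ErrorTally("all")
        for t in self.flowcells.values():
            out.add(t.mismatches, t.bases, t.pairs)
        return out

    # ----------------------------------------------------------- invariants

    def assert_conservation(self) -> None:
        """Tile sums == lane sums == surface sums == flow-cell totals, exactly."""
        def sums(table):
            by_fc: dict[str, list[int]] = {}
            for key, t in table.items():
                fc = key if isinstance(key, str) else key[0]
                acc = by_fc.setdefault(fc, [0, 0, 0])
                acc[0] += t.mismatches
                acc[1] += t.bases
                acc[2] += t.pairs
            return by_fc

        reference = sums(self.flowcells)
        for level in ("tile", "lane", "surface"):
            got = sums(self._table(level))
            if got != reference:
                raise AssertionError(
                    f"conservation violated at {level} level: {got} != {reference}")

    # ------------------------------------------------------------------ merge

    def merge(self, other: "RunTallies") -> "RunTallies":
        """Pool another run's integer counts into this one (exact)."""
        for level in ("tile", "lane", "surface", "flowcell"):
            mine = self._table(level)
            for key, t in other._table(level).items():
                tally = mine.get(key)
                if tally is None:
                    mine[key] = ErrorTally(key, t.mismatches, t.bases, t.pairs)
                else:
                    tally.add(t.mismatches, t.bases, t.pairs)
        for fc, inst in other.instruments.items():
            self.instruments.setdefault(fc, inst)
        n = other.cycle_count()
        self._ensure_cycles(n)
        for mate in ("fwd", "rev"):
            self._cycle_mism[mate][:n] += other._cycle_mism[mate][:n]
            self._cycle_bases[mate][:n] += other._cycle_bases[mate][:n]
            self._cycle_pairs[mate][:n] += other._cycle_pairs[mate][:n]
        return self


def surface_compare(tallies: RunTallies,
                    threshold_pm: float = OUTLIER_THRESHOLD_PM,
                    flag_fraction: float = 0.10,
                    tile_min_bases: int | None = None,
                    surface_min_bases: int | None = None) -> pd.DataFrame:
    """Per-flow-cell top/bottom comparison: surface rates and outlier-tile load.

    One row per (flowcell, surface) with the surface rate, the fraction of
    its sufficient tiles that are outliers, and a flag when that fraction
    exceeds ``flag_fraction`` (default 10%).
    """
    tile_ests = tallies.estimates("tile", tile_min_bases)
    surf_ests = tallies.estimates("surface", surface_min_bases)
    per_surface_tiles: dict[tuple, list[RateEstimate]] = {}
    for (fc, _lane, tile), est in tile_ests.items():
        surf = tallies._surface_of(tile)
        per_surface_tiles.setdefault((fc, surf), []).append(est)
    rows = []
    for (fc, surf), est in sorted(surf_ests.items()):
        tiles = per_surface_tiles.get((fc, surf), [])
        part = classify_outliers(tiles, threshold_pm)
        n_classified = len(part.outlier) + len(part.normal)
        frac = len(part.outlier) / n_classified if n_classified else nan
        rows.append({
            "flowcell": fc,
            "surface": surf,
            "mismatches": est.mismatches,
            "bases": est.bases,
            "rate_pm": est.rate_pm,
            "sufficient": est.sufficient,
            "n_tiles": len(tiles),
            "n_outlier_tiles": len(part.outlier),
            "n_insufficient_tiles": len(part.insufficient),
            "outlier_tile_fraction": frac,
            "flagged": bool(n_classified and frac > flag_fraction),
        })
    return pd.DataFrame(rows, columns=[
        "flowcell", "surface", "mismatches", "bases", "rate_pm", "sufficient",
        "n_tiles", "n_outlier_tiles", "n_insufficient_tiles",
        "outlier_tile_fraction", "flagged"])


def cycle_profile(tallies: RunTallies) -> pd.DataFrame:
    """Per-cycle rate series for each mate (forward and reverse reads).

    Cycles with zero included bases (e.g. trimmed cycles) have NaN rates and
    ``defined == False``; they are flagged, never reported as zero.
    """
    rows = []
    for mate in ("fwd", "rev"):
        bases = tallies._cycle_bases[mate]
        mism = tallies._cycle_mism[mate]
        for c in range(len(bases)):
            b = int(bases[c])
            rows.append({
                "mate": mate,
                "cycle": c + 1,
                "mismatches": int(mism[c]),
                "bases": b,
                "rate_pm": (mism[c] / b * 1e6) if b else nan,
                "defined": b > 0,
            })
    return pd.DataFrame(rows, columns=["mate", "cycle", "mismatches", "bases",
                                       "rate_pm", "defined"])


# ---------------------------------------------------------------------- I/O

_COUNT_COLUMNS = ["level", "flowcell", "instrument", "lane", "surface", "tile",
                  "mate", "cycle", "mismatches", "bases", "pairs"]


def write_counts(tallies: RunTallies, path) -> None:
    """Write the integer counts of every stratum as one tidy TSV."""
    rows = []

    def row(level, **kw):
        base = dict.fromkeys(_COUNT_COLUMNS, "")
        base["level"] = level
        base.update(kw)
        return base

    for (fc, lane, tile), t in sorted(tallies.tiles.items()):
        rows.append(row("tile", flowcell=fc, instrument=tallies.instruments.get(fc, ""),
                        lane=lane, tile=tile, mismatches=t.mismatches,
                        bases=t.bases, pairs=t.pairs))
    for (fc, lane), t in sorted(tallies.lanes.items()):
        rows.append(row("lane", flowcell=fc, lane=lane, mismatches=t.mismatches,
                        bases=t.bases, pairs=t.pairs))
    for (fc, surf), t in sorted(tallies.surfaces.items()):
        rows.append(row("surface", flowcell=fc, surface=surf,
                        mismatches=t.mismatches, bases=t.bases, pairs=t.pairs))
    for fc, t in sorted(tallies.flowcells.items()):
        rows.append(row("flowcell", flowcell=fc,
                        instrument=tallies.instruments.get(fc, ""),
                        mismatches=t.mismatches, bases=t.bases, pairs=t.pairs))
    for (mate, cycle), t in sorted(tallies._table("cycle").items()):
        rows.append(row("cycle", mate=mate, cycle=cycle, mismatches=t.mismatches,
                        bases=t.bases, pairs=t.pairs))
    pd.DataFrame(rows, columns=_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts(path, layout: FlowcellLayout | None = None) -> RunTallies:
    """Rebuild a :class:`RunTallies` from a counts TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"flowcell": str, "instrument": str,
                                            "mate": str}, keep_default_na=False)
    tallies = RunTallies(layout=layout)
    max_cycle = int(df.loc[df["level"] == "cycle", "cycle"].astype(int).max() or 0) \
        if (df["level"] == "cycle").any() else 0
    tallies._ensure_cycles(max_cycle)
    for rec in df.itertuples(index=False):
        m, b, p = int(rec.mismatches), int(rec.bases), int(rec.pairs)
        if rec.level == "tile":
            key = (rec.flowcell, int(rec.lane), int(rec.tile))
            tallies.tiles[key] = ErrorTally(key, m, b, p)
            if rec.instrument:
                tallies.instruments.setdefault(rec.flowcell, rec.instrument)
        elif rec.level == "lane":
            key = (rec.flowcell, int(rec.lane))
            tallies.lanes[key] = ErrorTally(key, m, b, p)
        elif rec.level == "surface":
            key = (rec.flowcell, int(rec.surface))
            tallies.surfaces[key] = ErrorTally(key, m, b, p)
        elif rec.level == "flowcell":
            tallies.flowcells[rec.flowcell] = ErrorTally(rec.flowcell, m, b, p)
            if rec.instrument:
                tallies.instruments.setdefault(rec.flowcell, rec.instrument)
        elif rec.level == "cycle":
            c = int(rec.cycle) - 1
            tallies._cycle_mism[rec.mate][c] = m
            tallies._cycle_bases[rec.mate][c] = b
            tallies._cycle_pairs[rec.mate][c] = p
        else:
            raise ValueError(f"unknown stratum level {rec.level!r} in {path}")
    return tallies


def merge_counts(paths, layout: FlowcellLayout | None = None) -> RunTallies:
    """Pool several counts TSVs into one :class:`RunTallies` (exact)."""
    merged = RunTallies(layout=layout)
    for p in paths:
        merged.merge(read_counts(p, layout=layout))
    return merged
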