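"""Computational suppression: remove reads from outlier tiles.

Suppression is read removal, not base correction: reads whose tile (or
whole surface) is flagged error-prone are dropped from the alignment file,
and everything downstream — pileups, rate estimates — simply sees less,
cleaner data.  Because both mates of a pair carry the same read name, and
hence the same tile, removing a tile never strands a mate: pair integrity
is preserved by construction, and re-suppressing an already-suppressed
file with the same set is a no-op.

Reads whose names cannot be parsed are KEPT by default (suppression must
be conservative: an unparseable name is no evidence the read is bad); set
``keep_unparseable=False`` to drop them instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .illumina import (FlowcellLayout, LayoutError, ReadNameError, decode_tile,
                       parse_read_name)

__all__ = ["TileSet", "SuppressReport", "suppress_tiles"]


@dataclass
class TileSet:
    """Outlier strata keyed by flow cell: individual tiles and/or whole
    surfaces (surface entries match every tile decoding to that surface)."""

    tiles: set = field(default_factory=set)        # {(flowcell, tile)}
    surfaces: set = field(default_factory=set)     # {(flowcell, surface)}
    layout: FlowcellLayout | None = None

    def __post_init__(self):
        self._surface_cache: dict[int, int] = {}

    def __len__(self) -> int:
        return len(self.tiles) + len(self.surfaces)

    def _surface_of(self, tile: int) -> int:
        surf = self._surface_cache.get(tile)
        if surf is None:
            layout = self.layout
            if layout is None:
                scheme = "SWCPP" if len(str(tile)) == 5 else "SWPP"
                layout = FlowcellLayout(swaths_per_lane=9, tiles_per_swath=99,
                                        tile_digit_scheme=scheme)
            try:
                surf = decode_tile(tile, layout).surface
            except LayoutError:
                surf = 0
            self._surface_cache[tile] = surf
        return surf

    def contains(self, flowcell: str, tile: int) -> bool:
        if (flowcell, tile) in self.tiles:
            return True
        if self.surfaces:
            return (flowcell, self._surface_of(tile)) in self.surfaces
        return False

    @classmethod
    def from_estimates(cls, estimates, layout: FlowcellLayout | None = None
                       ) -> "TileSet":
        """Build from outlier tile estimates keyed ``(flowcell, lane, tile)``
        or ``(flowcell, tile)`` (e.g. ``OutlierPartition.outlier``)."""
        out = cls(layout=layout)
        for est in estimates:
            key = getattr(est, "stratum", est)
            if len(key) == 3:
                fc, _lane, tile = key
            else:
                fc, tile = key
            out.tiles.add((fc, int(tile)))
        return out

    @classmethod
    def from_tsv(cls, path, layout: FlowcellLayout | None = None) -> "TileSet":
        """Read a two-column TSV (flowcell, tile); a tile value of
        ``surface:1`` or ``surface:2`` flags the whole surface."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"flowcell", "tile"} <= set(df.columns):
            raise ValueError(f"{path}: need columns 'flowcell' and 'tile'")
        out = cls(layout=layout)
        for rec in df.itertuples(index=False):
            tile = str(rec.tile).strip()
            if tile.startswith("surface:"):
                out.surfaces.add((rec.flowcell, int(tile.split(":", 1)[1])))
            else:
                out.tiles.add((rec.flowcell, int(tile)))
        return out

    def to_tsv(self, path) -> None:
        rows = [{"flowcell": fc, "tile": t} for fc, t in sorted(self.tiles)]
        rows += [{"flowcell": fc, "tile": f"surface:{s}"}
                 for fc, s in sorted(self.surfaces)]
        pd.DataFrame(rows, columns=["flowcell", "tile"]).to_csv(
            path, sep="\t", index=False)

    def describe(self) -> str:
        parts = [f"{fc}:{t}" for fc, t in sorted(self.tiles)]
        parts += [f"{fc}:surface{s}" for fc, s in sorted(self.surfaces)]
        return ",".join(parts) if parts else "none"


@dataclass
class SuppressReport:
    total_records: int = 0
    kept_records: int = 0
    removed_by_tile: Counter = field(default_factory=Counter)
    unparseable_kept: int = 0
    unparseable_removed: int = 0

    @property
    def removed_records(self) -> int:
        return self.total_records - self.kept_records

    def to_dict(self) -> dict:
        return {
            "total_records": self.total_records,
            "kept_records": self.kept_records,
            "removed_records": self.removed_records,
            "removed_by_tile": {f"{fc}:{tile}": int(n) for (fc, tile), n
                                in sorted(self.removed_by_tile.items())},
            "unparseable_kept": self.unparseable_kept,
            "unparseable_removed": self.unparseable_removed,
        }


def suppress_tiles(in_path, outliers, out_path,
                   keep_unparseable: bool = True) -> SuppressReport:
    """Copy an alignment file, dropping reads from outlier tiles.

    ``outliers`` is a :class:`TileSet` (or an iterable accepted by
    :meth:`TileSet.from_estimates`).  The output header gains a provenance
    ``@PG``/``@CO`` line naming the removed strata; the report counts
    removed reads per (flowcell, tile).  Output format follows the
    extension: ``.sam`` text, anything else BAM.
    """
    if not isinstance(outliers, TileSet):
        outliers = TileSet.from_estimates(outliers)
    report = SuppressReport()
    in_path, out_path = str(in_path), str(out_path)
    with pysam.AlignmentFile(in_path, check_sq=False) as src:
        header = src.header.to_dict()
        header.setdefault("PG", []).append(
            {"ID": "overlaperr-suppress", "PN": "overlaperr",
             "CL": f"suppress tiles={outliers.describe()}"})
        header.setdefault("CO", []).append(
            f"overlaperr suppress: removed strata {outliers.describe()}")
        mode = "w" if out_path.endswith(".sam") else "wb"
        with pysam.AlignmentFile(out_path, mode, header=header) as dst:
            for aln in src:
                report.total_records += 1
                try:
                    loc = parse_read_name(aln.query_name or "")
                except ReadNameError:
                    if keep_unparseable:
                        report.unparseable_kept += 1
                        dst.write(aln)
                        report.kept_records += 1
                    else:
                        report.unparseable_removed += 1
                    continue
                if outliers.contains(loc.flowcell, loc.tile):
                    report.removed_by_tile[(loc.flowcell, loc.tile)] += 1
                else:
                    dst.write(aln)
                    report.kept_records += 1
    return report
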