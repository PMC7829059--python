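"""Illumina read names and flow-cell geometry.

Illumina instruments encode the physical origin of every read in its name::

    <instrument>:<run>:<flowcell>:<lane>:<tile>:<x>:<y>

e.g. ``A00363:103:H3CMMDRXX:1:1101:21124:1000`` is a read from sequencer
A00363, run 103, flow cell H3CMMDRXX, lane 1, tile 1101.  The tile number is
itself a positional code whose digits name the flow-cell *surface* (1 = top,
2 = bottom), the *swath* (imaged column), an optional *camera* segment, and
the tile's *position* along the swath.  Error rates stratified by these
coordinates localise instrument problems to physical regions of the flow
cell, which is the point of this package.

Public archives (e.g. NCBI SRA) frequently rewrite read names to
``<accession>.<serial>``, destroying the location fields; such names raise
:class:`ReadNameError` and callers tally them rather than abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReadLocation",
    "TileCoordinate",
    "FlowcellLayout",
    "ReadNameError",
    "LayoutError",
    "parse_read_name",
    "decode_tile",
    "encode_tile",
    "layout_grid",
    "grid_table",
]


class ReadNameError(ValueError):
    """A read name that does not follow the 7-field Illumina convention."""

    def __init__(self, name: str, reason: str):
        self.read_name = name
        self.reason = reason
        super().__init__(f"unparseable read name {name!r}: {reason}")


class LayoutError(ValueError):
    """A tile number that does not fit the configured flow-cell layout."""


@dataclass(frozen=True, slots=True)
class ReadLocation:
    """Physical origin of a read, decoded from its name."""

    instrument: str
    run: int
    flowcell: str
    lane: int
    tile: int
    x: int
    y: int

    def name(self) -> str:
        """Re-serialize with ':' — inverse of :func:`parse_read_name`."""
        return (
            f"{self.instrument}:{self.run}:{self.flowcell}:"
            f"{self.lane}:{self.tile}:{self.x}:{self.y}"
        )


@dataclass(frozen=True, slots=True)
class TileCoordinate:
    """Decoded physical coordinate of a tile within a lane.

    ``camera`` is 0 on platforms whose tile numbers carry no camera digit.
    """

    surface: int
    swath: int
    camera: int
    position: int


# scheme letters: S surface, W swath, C camera, P position digit(s)
_SCHEME_CHARS = frozenset("SWCP")


@dataclass(frozen=True)
class FlowcellLayout:
    """Grid geometry of one flow-cell surface and the tile digit scheme.

    ``tile_digit_scheme`` assigns a meaning to each digit of the raw tile
    number, left to right: ``S`` surface, ``W`` swath, ``C`` camera, ``P``
    position (repeated for multi-digit positions).  The common 4-digit
    scheme is ``"SWPP"`` (tile 2159 -> surface 2, swath 1, position 59);
    platforms with a camera digit use ``"SWCPP"``.
    """

    platform: str = "custom"
    lanes: int = 1
    swaths_per_lane: int = 3
    tiles_per_swath: int = 24
    tile_digit_scheme: str = "SWPP"

    def __post_init__(self):
        s = self.tile_digit_scheme
        if not s or set(s) - _SCHEME_CHARS:
            raise LayoutError(f"invalid tile digit scheme {s!r}")
        for ch in "SW":
            if s.count(ch) != 1:
                raise LayoutError(f"scheme {s!r} must contain exactly one {ch!r}")
        if s.count("C") > 1:
            raise LayoutError(f"scheme {s!r} may contain at most one 'C'")
        if "P" not in s or "P" * s.count("P") not in s:
            raise LayoutError(f"position digits in {s!r} must be contiguous")
        if self.lanes < 1 or self.swaths_per_lane < 1 or self.tiles_per_swath < 1:
            raise LayoutError("lanes, swaths_per_lane, tiles_per_swath must be >= 1")

    # --- typical platform geometries (display defaults, overridable) ---

    @classmethod
    def hiseq(cls) -> "FlowcellLayout":
        return cls(platform="HiSeq", lanes=8, swaths_per_lane=3,
                   tiles_per_swath=24, tile_digit_scheme="SWPP")

    @classmethod
    def nextseq(cls) -> "FlowcellLayout":
        return cls(platform="NextSeq", lanes=4, swaths_per_lane=3,
                   tiles_per_swath=12, tile_digit_scheme="SWCPP")

    @classmethod
    def novaseq(cls) -> "FlowcellLayout":
        return cls(platform="NovaSeq", lanes=4, swaths_per_lane=6,
                   tiles_per_swath=78, tile_digit_scheme="SWPP")

    @classmethod
    def for_platform(cls, platform: str) -> "FlowcellLayout":
        key = platform.strip().lower()
        table = {"hiseq": cls.hiseq, "nextseq": cls.nextseq, "novaseq": cls.novaseq}
        if key not in table:
            raise LayoutError(f"unknown platform {platform!r}; use a layout config")
        return table[key]()

    @classmethod
    def from_dict(cls, d: Mapping) -> "FlowcellLayout":
        known = {"platform", "lanes", "swaths_per_lane", "tiles_per_swath",
                 "tile_digit_scheme"}
        base = {}
        if "platform" in d and set(d) == {"platform"}:
            return cls.for_platform(d["platform"])
        for k in d:
            if k not in known:
                raise LayoutError(f"unknown layout key {k!r}")
            base[k] = d[k]
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "FlowcellLayout":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise LayoutError(f"layout config {path} must be a mapping")
        return cls.from_dict(d)

    def tiles_per_surface(self) -> int:
        return self.lanes * self.swaths_per_lane * self.tiles_per_swath

    def all_tiles(self):
        """Every valid raw tile number under this layout (both surfaces)."""
        cameras = [0] if "C" not in self.tile_digit_scheme else list(range(1, 10))
        for surface in (1, 2):
            for swath in range(1, self.swaths_per_lane + 1):
                for camera in cameras:
                    for pos in range(1, self.tiles_per_swath + 1):
                        try:
                            yield encode_tile(
                                TileCoordinate(surface, swath, camera, pos), self)
                        except LayoutError:
                            continue


def parse_read_name(name: str) -> ReadLocation:
    """Parse a 7-field Illumina read name into a :class:`ReadLocation`.

    Anything after the first whitespace (a FASTQ comment / barcode field)
    is ignored.  Raises :class:`ReadNameError` on any deviation from the
    convention so that callers can tally-and-skip.
    """
    if not name:
        raise ReadNameError(name, "empty name")
    head = name.split(None, 1)[0] if (" " in name or "\t" in name) else name
    fields = head.split(":")
    if len(fields) != 7:
        raise ReadNameError(name, f"expected 7 ':'-delimited fields, got {len(fields)}")
    instrument, run_s, flowcell, lane_s, tile_s, x_s, y_s = fields
    if not instrument:
        raise ReadNameError(name, "empty instrument field")
    if not flowcell:
        raise ReadNameError(name, "empty flowcell field")
    ints = {}
    for label, raw in (("run", run_s), ("lane", lane_s), ("tile", tile_s),
                       ("x", x_s), ("y", y_s)):
        if not raw.isdigit():
            raise ReadNameError(name, f"non-numeric {label} field {raw!r}")
        ints[label] = int(raw)
    if ints["lane"] < 1:
        raise ReadNameError(name, "lane must be >= 1")
    if ints["tile"] < 1:
        raise ReadNameError(name, "tile must be >= 1")
    return ReadLocation(instrument, ints["run"], flowcell, ints["lane"],
                        ints["tile"], ints["x"], ints["y"])


def decode_tile(tile: int, layout: FlowcellLayout) -> TileCoordinate:
    """Decode a raw tile number into surface/swath/camera/position."""
    scheme = layout.tile_digit_scheme
    s = str(tile)
    if len(s) != len(scheme):
        raise LayoutError(
            f"tile {tile} has {len(s)} digits; scheme {scheme!r} expects {len(scheme)}")
    parts = {"S": "", "W": "", "C": "", "P": ""}
    for ch, digit in zip(scheme, s):
        parts[ch] += digit
    surface = int(parts["S"])
    swath = int(parts["W"])
    camera = int(parts["C"]) if parts["C"] else 0
    position = int(parts["P"])
    if surface not in (1, 2):
        raise LayoutError(f"tile {tile}: surface digit {surface} not in {{1, 2}}")
    if not (1 <= swath <= layout.swaths_per_lane):
        raise LayoutError(
            f"tile {tile}: swath {swath} outside 1..{layout.swaths_per_lane}")
    if not (1 <= position <= layout.tiles_per_swath):
        raise LayoutError(
            f"tile {tile}: position {position} outside 1..{layout.tiles_per_swath}")
    if parts["C"] and camera < 1:
        raise LayoutError(f"tile {tile}: camera digit must be >= 1")
    return TileCoordinate(surface, swath, camera, position)


def encode_tile(coord: TileCoordinate, layout: FlowcellLayout) -> int:
    """Inverse of :func:`decode_tile` for valid coordinates."""
    scheme = layout.tile_digit_scheme
    widths = {ch: scheme.count(ch) for ch in "SWCP"}
    values = {"S": coord.surface, "W": coord.swath, "C": coord.camera,
              "P": coord.position}
    out = []
    done = set()
    for ch in scheme:
        if ch in done:
            continue
        done.add(ch)
        text = str(values[ch])
        if len(text) > widths[ch]:
            raise LayoutError(
                f"{ch}-field value {values[ch]} does not fit {widths[ch]} digit(s)")
        out.append(text.zfill(widths[ch]))
    tile = int("".join(out))
    if str(tile) != "".join(out):  # leading zero (e.g. surface 0)
        raise LayoutError(f"coordinate {coord} encodes with a leading zero")
    return tile


def _normalize_tile_key(key):
    """Accept raw tile numbers or (lane, tile) pairs as grid keys."""
    if isinstance(key, tuple):
        lane, tile = key
        return int(lane), int(tile)
    return 1, int(key)


def layout_grid(layout: FlowcellLayout, tile_rates: Mapping) -> dict[int, np.ndarray]:
    """Place per-tile rates on the physical grid of each surface.

    ``tile_rates`` maps a raw tile number (or a ``(lane, tile)`` pair) to a
    rate estimate (anything with a ``rate_pm`` attribute, or a plain number).
    Returns ``{surface: array}`` with one row per (lane, swath) and one
    column per position; cells without data are NaN, never zero.  Rates are
    NOT capped here — capping is a display-time choice of the plotting code.
    """
    rows = layout.lanes * layout.swaths_per_lane
    grids = {1: np.full((rows, layout.tiles_per_swath), np.nan),
             2: np.full((rows, layout.tiles_per_swath), np.nan)}
    for key, est in tile_rates.items():
        lane, tile = _normalize_tile_key(key)
        coord = decode_tile(tile, layout)
        if not (1 <= lane <= layout.lanes):
            raise LayoutError(f"lane {lane} outside 1..{layout.lanes}")
        rate = getattr(est, "rate_pm", est)
        row = (lane - 1) * layout.swaths_per_lane + (coord.swath - 1)
        grids[coord.surface][row, coord.position - 1] = float(rate)
    return grids


def grid_table(layout: FlowcellLayout, tile_rates: Mapping) -> pd.DataFrame:
    """Tidy export of the tile grid: one row per tile with its coordinates."""
    records = []
    for key, est in sorted(tile_rates.items(), key=lambda kv: _normalize_tile_key(kv[0])):
        lane, tile = _normalize_tile_key(key)
        coord = decode_tile(tile, layout)
        records.append({
            "surface": coord.surface,
            "lane": lane,
            "swath": coord.swath,
            "camera": coord.camera,
            "position": coord.position,
            "tile": tile,
            "rate_pm": float(getattr(est, "rate_pm", est)),
            "bases": int(getattr(est, "bases", 0)),
            "mismatches": int(getattr(est, "mismatches", 0)),
        })
    cols = ["surface", "lane", "swath", "camera", "position", "tile",
            "rate_pm", "bases", "mismatches"]
    return pd.DataFrame.from_records(records, columns=cols)
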