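"""Read- and base-level quality gates.

Discordances between overlapping mates are only attributable to the
instrument if alignment and base-call artifacts are excluded first.  The
gate applies six rules, in a fixed order, to each aligned record:

1. the read must be mapped, primary, and (by default) properly paired;
2. mapping quality must lie in [mapq_min, mapq_max] (default 55..254 —
   MAPQ 255 means "unavailable" and is rejected);
3. the CIGAR must be a single match run (``^\\d+M$``): no indels, clips or
   splices, so reference coordinates map linearly onto sequencing cycles;
4. fewer than ``max_lowq_base_fraction`` of the read's bases may have
   Phred < ``lowq_phred`` (default: < 5% below Q20), evaluated on the full
   read before any trimming;
5. individual bases with Phred < ``base_phred_min`` (default Q30), and N
   calls, are excluded even when the read is kept;
6. the first ``end_trim`` sequencing cycles of each mate (default 5) are
   excluded for the well-known quality drop at the start of a read.

"Sequencing cycle" is the position in the order the instrument read the
base: cycle 1 is the 5' end of the raw read, which for a reverse-strand
alignment is the *last* base in reference orientation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "FilterConfig",
    "FilterReason",
    "FilterVerdict",
    "read_gate",
    "base_mask",
    "query_cycles",
]

_SIMPLE_CIGAR = re.compile(r"^\d+M$")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the quality gate; defaults are the suppression mode."""

    mapq_min: int = 55
    mapq_max: int = 254
    max_lowq_base_fraction: float = 0.05
    lowq_phred: int = 20
    base_phred_min: int = 30
    end_trim: int = 5
    require_proper_pair: bool = True
    exclude_duplicates: bool = False

    def __post_init__(self):
        if not (0 <= self.mapq_min <= self.mapq_max <= 254):
            raise ValueError("need 0 <= mapq_min <= mapq_max <= 254")
        if not (0 <= self.max_lowq_base_fraction <= 1):
            raise ValueError("max_lowq_base_fraction must be in [0, 1]")
        if self.end_trim < 0:
            raise ValueError("end_trim must be >= 0")

    @classmethod
    def relaxed(cls) -> "FilterConfig":
        """No-suppression mode: every mapped, proper, simple-CIGAR pair passes
        and every called base is included."""
        return cls(mapq_min=0, mapq_max=254, max_lowq_base_fraction=1.0,
                   lowq_phred=0, base_phred_min=0, end_trim=0)

    def with_overrides(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


class FilterReason(str, Enum):
    OK = "ok"
    UNMAPPED = "unmapped"
    SECONDARY_OR_SUPPLEMENTARY = "secondary_or_supplementary"
    QCFAIL = "qcfail"
    DUPLICATE = "duplicate"
    NOT_PROPER_PAIR = "not_proper_pair"
    MAPQ = "mapq"
    CIGAR = "cigar"
    LOWQ_FRACTION = "lowq_fraction"
    NAME_UNPARSEABLE = "name_unparseable"


@dataclass(frozen=True, slots=True)
class FilterVerdict:
    passed: bool
    reason: FilterReason

    def __post_init__(self):
        assert self.passed == (self.reason is FilterReason.OK)


_PASS = FilterVerdict(True, FilterReason.OK)


def read_gate(aln, cfg: FilterConfig | None = None) -> FilterVerdict:
    """Apply the read-level rules to one aligned record.

    Rules are evaluated in a fixed order and the verdict carries the FIRST
    failing reason, so identical records always yield identical verdicts.
    Raises ``ValueError`` if base qualities are absent (the low-quality
    fraction rule cannot be evaluated).
    """
    if cfg is None:
        cfg = FilterConfig()
    if aln.is_unmapped:
        return FilterVerdict(False, FilterReason.UNMAPPED)
    if aln.is_secondary or aln.is_supplementary:
        return FilterVerdict(False, FilterReason.SECONDARY_OR_SUPPLEMENTARY)
    if aln.is_qcfail:
        return FilterVerdict(False, FilterReason.QCFAIL)
    if cfg.exclude_duplicates and aln.is_duplicate:
        return FilterVerdict(False, FilterReason.DUPLICATE)
    if cfg.require_proper_pair and not aln.is_proper_pair:
        return FilterVerdict(False, FilterReason.NOT_PROPER_PAIR)
    if not (cfg.mapq_min <= aln.mapping_quality <= cfg.mapq_max):
        return FilterVerdict(False, FilterReason.MAPQ)
    cig = aln.cigarstring
    if cig is None or not _SIMPLE_CIGAR.match(cig):
        return FilterVerdict(False, FilterReason.CIGAR)
    quals = aln.query_qualities
    if quals is None:
        raise ValueError(
            f"read {aln.query_name!r} has no base qualities; "
            "the low-quality-fraction rule cannot be evaluated")
    if cfg.max_lowq_base_fraction < 1.0:
        q = np.frombuffer(quals, dtype=np.uint8)
        # fast path: no base below the threshold
        if q.min() < cfg.lowq_phred:
            frac = np.count_nonzero(q < cfg.lowq_phred) / len(q)
            if not frac < cfg.max_lowq_base_fraction:
                return FilterVerdict(False, FilterReason.LOWQ_FRACTION)
    return _PASS


def query_cycles(aln) -> np.ndarray:
    """Sequencing cycle (1-based) of each query position, in the alignment
    (reference-forward) orientation in which pysam stores the sequence."""
    n = len(aln.query_qualities)
    if aln.is_reverse:
        return np.arange(n, 0, -1)
    return np.arange(1, n + 1)


def base_mask(aln, cfg: FilterConfig | None = None) -> np.ndarray:
    """Per-cycle inclusion mask for a read that passed :func:`read_gate`.

    ``mask[c - 1]`` is True iff sequencing cycle ``c`` is included: the
    cycle is beyond the end trim, its Phred is >= ``base_phred_min`` and
    the call is not N.  :func:`query_cycles` maps alignment-orientation
    query positions onto cycles (and, for a simple-CIGAR read, query
    position i sits at reference position ``reference_start + i``).
    """
    if cfg is None:
        cfg = FilterConfig()
    quals = np.frombuffer(aln.query_qualities, dtype=np.uint8)
    seq = np.frombuffer(aln.query_sequence.encode("ascii"), dtype=np.uint8)
    include = (quals >= cfg.base_phred_min) & (seq != ord("N"))
    if aln.is_reverse:
        include = include[::-1]  # index by cycle, not query position
    if cfg.end_trim:
        include = include.copy()
        include[: cfg.end_trim] = False
    return include
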