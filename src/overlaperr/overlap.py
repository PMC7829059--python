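"""Per-pair overlap discordance counting.

When the sequenced fragment is shorter than twice the read length, the
forward and reverse mates read the middle of the fragment twice.  Any
template-level event — a true variant, a PCR misincorporation — is copied
into BOTH reads, so within the overlap the two base calls can only differ
if the instrument mis-called one of them.  For a pair *r* the overlap
contributes ``2*n_r`` sequenced bases (``n_r`` positions read twice) and
``m_r`` discordant positions, and the sequencer error rate of any stratum
is ``sum(m_r) / sum(2*n_r)`` over the pairs in it.

Positions enter the tally only when the base from *each* mate survives the
base-level gate (Q30, no N, end trim); a half-passing position cannot be
checked for concordance and contributes to neither numerator nor
denominator.  Bases are compared in reference orientation as stored in the
alignment, so strand complementarity is already resolved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

from .filters import FilterConfig, FilterReason, read_gate
from .illumina import ReadLocation, ReadNameError, parse_read_name

__all__ = ["PairOverlap", "PairingError", "PairStreamStats", "compute_overlap",
           "pair_stream"]

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_B = np.empty(0, dtype=bool)


class PairingError(ValueError):
    """Mates that cannot form a pair (different reference or name)."""


@dataclass(slots=True)
class PairOverlap:
    """Overlap tally for one read pair.

    ``fwd_cycles[i]`` / ``rev_cycles[i]`` are the sequencing cycles at which
    each mate read the i-th included overlap position; ``discordant[i]``
    says whether the two calls differed there.  Which mate erred is
    unknowable, so a discordance charges both mates' cycles downstream.
    """

    n_r: int
    m_r: int
    fwd_cycles: np.ndarray
    rev_cycles: np.ndarray
    discordant: np.ndarray
    location: ReadLocation | None = None
    ref_name: str | None = None

    @property
    def fwd_cycle_flags(self) -> list[tuple[int, bool]]:
        return list(zip(self.fwd_cycles.tolist(), self.discordant.tolist()))

    @property
    def rev_cycle_flags(self) -> list[tuple[int, bool]]:
        return list(zip(self.rev_cycles.tolist(), self.discordant.tolist()))

    @property
    def sequenced_bases(self) -> int:
        return 2 * self.n_r


def _mate_arrays(aln, lo: int, hi: int, cfg: FilterConfig):
    """Sequence, inclusion mask and cycle numbers over reference span [lo, hi)."""
    start = aln.reference_start
    i0, i1 = lo - start, hi - start
    seq = np.frombuffer(aln.query_sequence.encode("ascii"), dtype=np.uint8)[i0:i1]
    quals = np.frombuffer(aln.query_qualities, dtype=np.uint8)[i0:i1]
    n = len(aln.query_qualities)
    idx = np.arange(i0, i1, dtype=np.int64)
    cycles = (n - idx) if aln.is_reverse else (idx + 1)
    include = (quals >= cfg.base_phred_min) & (seq != ord("N")) & (cycles > cfg.end_trim)
    return seq, include, cycles


def compute_overlap(fwd, rev, cfg: FilterConfig | None = None,
                    location: ReadLocation | None = None) -> PairOverlap:
    """Tally included and discordant positions in the overlap of two mates.

    Both mates must already have passed :func:`~overlaperr.filters.read_gate`
    (in particular they carry single-match-run CIGARs, so each covers one
    contiguous reference span).  A zero-length overlap yields
    ``n_r = m_r = 0``.
    """
    if cfg is None:
        cfg = FilterConfig()
    if fwd.reference_name != rev.reference_name:
        raise PairingError(
            f"mates of {fwd.query_name!r} on different references "
            f"({fwd.reference_name} vs {rev.reference_name})")
    if fwd.query_name != rev.query_name:
        raise PairingError(
            f"read name mismatch: {fwd.query_name!r} vs {rev.query_name!r}")
    lo = max(fwd.reference_start, rev.reference_start)
    hi = min(fwd.reference_end, rev.reference_end)
    if location is None and fwd.query_name:
        try:
            location = parse_read_name(fwd.query_name)
        except ReadNameError:
            location = None
    if hi <= lo:
        return PairOverlap(0, 0, _EMPTY_I, _EMPTY_I, _EMPTY_B,
                           location=location, ref_name=fwd.reference_name)
    seq_f, inc_f, cyc_f = _mate_arrays(fwd, lo, hi, cfg)
    seq_r, inc_r, cyc_r = _mate_arrays(rev, lo, hi, cfg)
    included = inc_f & inc_r
    discord = included & (seq_f != seq_r)
    n_r = int(np.count_nonzero(included))
    m_r = int(np.count_nonzero(discord))
    return PairOverlap(
        n_r=n_r,
        m_r=m_r,
        fwd_cycles=cyc_f[included],
        rev_cycles=cyc_r[included],
        discordant=discord[included],
        location=location,
        ref_name=fwd.reference_name,
    )


@dataclass
class PairStreamStats:
    """Bookkeeping for one pass over an alignment stream."""

    records: int = 0
    secondary_or_supplementary: int = 0
    pairs_emitted: int = 0
    pairs_skipped: Counter = field(default_factory=Counter)
    unparseable_pairs: int = 0
    orphans: int = 0

    @property
    def pairs_seen(self) -> int:
        return self.pairs_emitted + sum(self.pairs_skipped.values())

    @property
    def unparseable_fraction(self) -> float:
        seen = self.pairs_seen
        return self.unparseable_pairs / seen if seen else 0.0

    def to_dict(self) -> dict:
        return {
            "records": self.records,
            "secondary_or_supplementary": self.secondary_or_supplementary,
            "pairs_emitted": self.pairs_emitted,
            "pairs_skipped": {k: int(v) for k, v in sorted(self.pairs_skipped.items())},
            "unparseable_pairs": self.unparseable_pairs,
            "unparseable_fraction": self.unparseable_fraction,
            "orphans": self.orphans,
        }


def _open_alignments(source):
    if isinstance(source, pysam.AlignmentFile):
        return source, False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        return pysam.AlignmentFile(str(source), check_sq=False), True
    return source, False  # already an iterable of records


def pair_stream(source, cfg: FilterConfig | None = None,
                stats: PairStreamStats | None = None,
                max_buffer: int = 2_000_000) -> Iterator[PairOverlap]:
    """Yield one :class:`PairOverlap` per QC-passing read pair.

    ``source`` may be a SAM/BAM path, an open ``pysam.AlignmentFile`` or an
    iterable of records.  Mates are matched by read name with a bounded
    in-memory buffer, so coordinate- or name-sorted input both work for
    ordinary insert sizes; if the buffer exceeds ``max_buffer`` waiting
    mates, a ``MemoryError`` advises name-collating the input first.

    Pairs in which either mate fails the gate are counted in
    ``stats.pairs_skipped`` under the first failing reason; pairs whose
    names cannot be parsed are counted as unparseable and skipped.
    """
    if cfg is None:
        cfg = FilterConfig()
    if stats is None:
        stats = PairStreamStats()
    alignments, owned = _open_alignments(source)
    pending: dict[str, object] = {}
    try:
        for aln in alignments:
            stats.records += 1
            if aln.is_secondary or aln.is_supplementary:
                stats.secondary_or_supplementary += 1
                continue
            if not aln.is_paired:
                stats.orphans += 1
                continue
            name = aln.query_name
            mate = pending.pop(name, None)
            if mate is None:
                if len(pending) >= max_buffer:
                    raise MemoryError(
                        f"more than {max_buffer} reads awaiting their mate; "
                        "collate the input by read name and retry")
                pending[name] = aln
                continue
            first, second = (mate, aln) if mate.is_read1 else (aln, mate)
            v1 = read_gate(first, cfg)
            v2 = read_gate(second, cfg)
            if not v1.passed or not v2.passed:
                reason = v1.reason if not v1.passed else v2.reason
                stats.pairs_skipped[reason.value] += 1
                continue
            try:
                location = parse_read_name(name)
            except ReadNameError:
                stats.pairs_skipped[FilterReason.NAME_UNPARSEABLE.value] += 1
                stats.unparseable_pairs += 1
                continue
            try:
                ov = compute_overlap(first, second, cfg, location=location)
            except PairingError:
                stats.pairs_skipped["pairing_error"] += 1
                continue
            stats.pairs_emitted += 1
            yield ov
        stats.orphans += len(pending)
    finally:
        if owned:
            alignments.close()
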