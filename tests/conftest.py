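"""Shared fixtures: in-memory alignment records and SAM writers."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from overlaperr.filters import FilterConfig, base_mask

HEADER_DICT = {
    "HD": {"VN": "1.6"},
    "SQ": [{"SN": "ref1", "LN": 100000}, {"SN": "ref2", "LN": 100000}],
}
HEADER = pysam.AlignmentHeader.from_dict(HEADER_DICT)

DEFAULT_NAME = "M:0:F:1:1101:0:0"


def make_read(name: str = DEFAULT_NAME, start: int = 100, seq: str | None = None,
              quals=37, length: int = 100, mapq: int = 60,
              cigar: str | None = None, reverse: bool = False,
              read1: bool = True, proper: bool = True, paired: bool = True,
              unmapped: bool = False, secondary: bool = False,
              supplementary: bool = False, duplicate: bool = False,
              qcfail: bool = False, ref_id: int = 0,
              no_quals: bool = False) -> pysam.AlignedSegment:
    """Build one aligned record with sensible defaults (Q37, simple CIGAR)."""
    a = pysam.AlignedSegment(header=HEADER)
    a.query_name = name
    if seq is None:
        seq = "A" * length
    a.query_sequence = seq
    flag = 0
    if paired:
        flag |= 0x1 | (0x40 if read1 else 0x80)
        if proper:
            flag |= 0x2
    if unmapped:
        flag |= 0x4
    if reverse:
        flag |= 0x10
    if secondary:
        flag |= 0x100
    if qcfail:
        flag |= 0x200
    if duplicate:
        flag |= 0x400
    if supplementary:
        flag |= 0x800
    a.flag = flag
    if not unmapped:
        a.reference_id = ref_id
        a.reference_start = start
        a.mapping_quality = mapq
        a.cigarstring = cigar if cigar is not None else f"{len(seq)}M"
    if not no_quals:
        if isinstance(quals, int):
            quals = [quals] * len(seq)
        a.query_qualities = np.asarray(quals, dtype=np.uint8).tolist()
    return a


def make_pair(name: str = DEFAULT_NAME, fwd_start: int = 100,
              rev_start: int = 130, length: int = 100,
              fwd_seq: str | None = None, rev_seq: str | None = None,
              fwd_quals=37, rev_quals=37, **kw):
    """A proper pair: read1 forward, read2 reverse."""
    fwd = make_read(name=name, start=fwd_start, seq=fwd_seq, quals=fwd_quals,
                    length=length, read1=True, reverse=False, **kw)
    rev = make_read(name=name, start=rev_start, seq=rev_seq, quals=rev_quals,
                    length=length, read1=False, reverse=True, **kw)
    return fwd, rev


def write_sam(path, records, header: dict | None = None) -> str:
    """Write records to a SAM file and return its path as str."""
    with pysam.AlignmentFile(str(path), "w",
                             header=header or HEADER_DICT) as fh:
        for rec in records:
            fh.write(rec)
    return str(path)


def brute_force_overlap(fwd, rev, cfg: FilterConfig | None = None):
    """Independent oracle: walk every reference position of both spans and
    compare characters, using only the public base mask."""
    if cfg is None:
        cfg = FilterConfig()
    mf = base_mask(fwd, cfg)
    mr = base_mask(rev, cfg)
    n = m = 0
    lo = min(fwd.reference_start, rev.reference_start)
    hi = max(fwd.reference_end, rev.reference_end)
    for pos in range(lo, hi):
        fi = pos - fwd.reference_start
        ri = pos - rev.reference_start
        if not (0 <= fi < len(fwd.query_sequence)):
            continue
        if not (0 <= ri < len(rev.query_sequence)):
            continue
        fcyc = len(fwd.query_sequence) - fi if fwd.is_reverse else fi + 1
        rcyc = len(rev.query_sequence) - ri if rev.is_reverse else ri + 1
        if not (mf[fcyc - 1] and mr[rcyc - 1]):
            continue
        n += 1
        if fwd.query_sequence[fi] != rev.query_sequence[ri]:
            m += 1
    return n, m


def random_pair(rng: np.random.Generator, length: int = 60):
    """A random proper pair with random sequences, qualities and offsets."""
    fwd_start = int(rng.integers(0, 50))
    rev_start = fwd_start + int(rng.integers(-length, length + 20))
    rev_start = max(rev_start, 0)
    bases = "ACGTN"
    fwd_seq = "".join(rng.choice(list(bases), size=length, p=[.24, .24, .24, .24, .04]))
    rev_seq = "".join(rng.choice(list(bases), size=length, p=[.24, .24, .24, .24, .04]))
    fwd_quals = rng.integers(2, 41, size=length).tolist()
    rev_quals = rng.integers(2, 41, size=length).tolist()
    return make_pair(fwd_start=fwd_start, rev_start=rev_start, length=length,
                     fwd_seq=fwd_seq, rev_seq=rev_seq,
                     fwd_quals=fwd_quals, rev_quals=rev_quals)


@pytest.fixture
def pair_factory():
    return make_pair


@pytest.fixture
def read_factory():
    return make_read
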