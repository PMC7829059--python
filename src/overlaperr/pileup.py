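"""Site-specific overall error rates from deep pileups.

The overall error rate (oER) at a genomic site is the fraction of reads
carrying each non-dominant base: with called wild-type allele ``g`` and a
mismatch base ``m``,

    oER_i(g > m) = (# reads with m at site i) / (total # reads at site i).

Unlike the overlap-discordance rate, the oER mixes every error source —
true cellular mutations, PCR misincorporations and instrument errors — so
comparing oER with and without outlier-tile suppression quantifies how
much of it the instrument contributed.  Genotypes follow the deep-pileup
convention: a site is *callable* when its post-filter depth exceeds 10 and
one allele holds more than 95% of the reads; the called dominant allele
(not the reference FASTA base) plays the wild-type role ``g``.

Bases enter the pileup only if their read passes the read gate and the
base passes the base-level mask, mirroring the overlap counter's filters;
reads from excluded tiles are skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta
from scipy import stats

from .filters import FilterConfig, read_gate
from .illumina import ReadNameError, parse_read_name
from .suppress import TileSet

__all__ = [
    "SiteCounts",
    "OERRecord",
    "SUBSTITUTION_CLASSES",
    "substitution_class",
    "pileup",
    "oer",
    "site_oer_records",
    "compare_runs",
    "CompareResult",
    "write_sites",
    "read_sites",
    "read_bed",
    "read_spikeins",
]

_ALLELES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# the 12 substitutions collapse into 6 complementary-strand classes
SUBSTITUTION_CLASSES = ("A>C/T>G", "A>G/T>C", "A>T/T>A",
                        "C>A/G>T", "C>G/G>C", "C>T/G>A")


def substitution_class(g: str, m: str) -> str:
    """Complementary-pair label of one substitution, e.g. T>G -> 'A>C/T>G'."""
    if g in "AC":
        label = f"{g}>{m}/{_COMP[g]}>{_COMP[m]}"
    else:
        label = f"{_COMP[g]}>{_COMP[m]}/{g}>{m}"
    if label not in SUBSTITUTION_CLASSES:
        raise ValueError(f"not a substitution: {g}>{m}")
    return label


@dataclass(frozen=True, slots=True)
class SiteCounts:
    """Post-filter allele counts at one reference position (1-based)."""

    ref_name: str
    pos: int
    ref_allele: str
    counts: tuple  # (A, C, G, T)
    depth: int
    dominant: str
    dominant_fraction: float
    callable: bool

    def count(self, allele: str) -> int:
        return self.counts[_ALLELES.index(allele)]


@dataclass(frozen=True, slots=True)
class OERRecord:
    ref_name: str
    pos: int
    substitution: str   # "g>m", g = called dominant allele
    rate: float
    paired_type: str    # complementary-strand class label


def _make_site(ref_name: str, pos: int, ref_allele: str, counts: np.ndarray,
               min_depth: int, min_dominant_fraction: float) -> SiteCounts:
    depth = int(counts.sum())
    dom_i = int(counts.argmax())  # ties break in A<C<G<T order
    dominant = _ALLELES[dom_i]
    frac = counts[dom_i] / depth if depth else 0.0
    return SiteCounts(
        ref_name=ref_name,
        pos=pos,
        ref_allele=ref_allele,
        counts=tuple(int(c) for c in counts),
        depth=depth,
        dominant=dominant,
        dominant_fraction=float(frac),
        callable=bool(depth > min_depth and frac > min_dominant_fraction),
    )


def read_bed(path) -> list[tuple[str, int, int]]:
    """(ref, start, end) triples from a BED file (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["ref", "start", "end"],
                     dtype={"ref": str})
    return [(r.ref, int(r.start), int(r.end)) for r in df.itertuples(index=False)]


def read_spikeins(path) -> list[tuple[str, int, str, str]]:
    """(ref_name, 1-based pos, ref, alt) rows from a spike-in TSV."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    need = ["ref_name", "pos", "ref", "alt"]
    if not all(k in cols for k in need):
        raise ValueError(f"{path}: need columns {need}")
    return [(str(getattr(r, cols["ref_name"])), int(getattr(r, cols["pos"])),
             str(getattr(r, cols["ref"])), str(getattr(r, cols["alt"])))
            for r in df.itertuples(index=False)]


_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


def pileup(alignments, reference, regions=None, cfg: FilterConfig | None = None,
           excluded_tiles: TileSet | None = None, min_depth: int = 10,
           min_dominant_fraction: float = 0.95,
           keep_unparseable: bool = True) -> dict[tuple[str, int], SiteCounts]:
    """Per-site filtered allele counts over the given regions.

    ``alignments`` is a SAM/BAM path or open file; ``reference`` a FASTA
    path or ``pyfaidx.Fasta``; ``regions`` an optional BED path or list of
    (ref, start, end) 0-based half-open triples (default: every reference
    sequence the alignments cover).  N calls are never counted.  With
    ``excluded_tiles`` set, reads from those tiles are skipped entirely;
    reads with unparseable names are kept unless ``keep_unparseable`` is
    False (mirroring the conservative suppression default).

    Returns an ordered dict keyed by (ref_name, 1-based position) for every
    position with nonzero depth.
    """
    if cfg is None:
        cfg = FilterConfig()
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    if regions is None:
        region_list = None
    elif isinstance(regions, (str, bytes)) or hasattr(regions, "__fspath__"):
        region_list = read_bed(regions)
    else:
        region_list = list(regions)
    if region_list is not None:
        for ref, start, end in region_list:
            if ref not in fasta:
                raise ValueError(f"region reference {ref!r} not in FASTA")
            if not (0 <= start < end <= len(fasta[ref])):
                raise ValueError(f"region {ref}:{start}-{end} outside reference")

    own = isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__")
    af = pysam.AlignmentFile(str(alignments), check_sq=False) if own else alignments
    try:
        if region_list is None:
            # default to whatever the alignments and the FASTA both cover
            region_list = [(name, 0, min(length, len(fasta[name])))
                           for name, length in zip(af.references, af.lengths)
                           if name in fasta]
        counters = {}
        for ref, start, end in region_list:
            counters.setdefault(ref, []).append(
                (start, end, np.zeros((end - start, 4), dtype=np.int64)))

        def feed(aln):
            if read_gate(aln, cfg).passed is False:
                return
            if excluded_tiles is not None or not keep_unparseable:
                try:
                    loc = parse_read_name(aln.query_name or "")
                except ReadNameError:
                    if not keep_unparseable:
                        return
                    loc = None
                if (loc is not None and excluded_tiles is not None
                        and excluded_tiles.contains(loc.flowcell, loc.tile)):
                    return
            blocks = counters.get(aln.reference_name)
            if not blocks:
                return
            seq = np.frombuffer(aln.query_sequence.encode("ascii"), np.uint8)
            quals = np.frombuffer(aln.query_qualities, np.uint8)
            n = len(seq)
            idx = np.arange(n, dtype=np.int64)
            cycles = (n - idx) if aln.is_reverse else (idx + 1)
            base_i = _BASE_LUT[seq]
            ok = (quals >= cfg.base_phred_min) & (base_i >= 0) & \
                 (cycles > cfg.end_trim)
            rs = aln.reference_start
            refpos = rs + idx
            for start, end, counts in blocks:
                sel = ok & (refpos >= start) & (refpos < end)
                if sel.any():
                    counts[refpos[sel] - start, base_i[sel]] += 1

        use_fetch = own and af.has_index()
        if use_fetch:
            for ref, start, end in region_list:
                for aln in af.fetch(ref, start, end):
                    feed(aln)
        else:
            for aln in af:
                if not aln.is_unmapped:
                    feed(aln)
    finally:
        if own:
            af.close()

    sites: dict[tuple[str, int], SiteCounts] = {}
    for ref, start, end in region_list:
        refseq = str(fasta[ref][start:end]).upper()
        for s, e, counts in counters[ref]:
            if (s, e) != (start, end):
                continue
            nz = np.nonzero(counts.sum(axis=1))[0]
            for off in nz:
                pos = start + int(off) + 1
                sites[(ref, pos)] = _make_site(
                    ref, pos, refseq[off], counts[off],
                    min_depth, min_dominant_fraction)
            break
    return sites


def oer(site: SiteCounts, m: str) -> OERRecord:
    """One substitution's overall error rate at a callable site."""
    if not site.callable:
        raise ValueError(
            f"site {site.ref_name}:{site.pos} is not callable "
            f"(depth {site.depth}, dominant fraction {site.dominant_fraction:.3f})")
    if m == site.dominant:
        raise ValueError(f"{m} is the dominant allele at {site.ref_name}:{site.pos}")
    g = site.dominant
    return OERRecord(
        ref_name=site.ref_name,
        pos=site.pos,
        substitution=f"{g}>{m}",
        rate=site.count(m) / site.depth,
        paired_type=substitution_class(g, m),
    )


def site_oer_records(site: SiteCounts) -> list[OERRecord]:
    """The three substitution records of one callable site."""
    return [oer(site, m) for m in _ALLELES if m != site.dominant]


@dataclass
class CompareResult:
    """Outcome of a with/without comparison of two pileups over shared sites."""

    summary: pd.DataFrame    # one row per substitution class
    sites: pd.DataFrame      # one row per (site, substitution)
    spikeins: pd.DataFrame   # one row per spike-in site


def compare_runs(a: Mapping, b: Mapping,
                 spikeins: Iterable[tuple[str, int, str, str]] | None = None
                 ) -> CompareResult:
    """Paired per-substitution comparison of two pileups of the same sites.

    ``a`` is the baseline and ``b`` the comparison arm (e.g. after
    outlier-tile suppression); both map (ref_name, pos) to
    :class:`SiteCounts`.  Only sites callable in both arms and agreeing on
    the dominant allele enter the per-class statistics; spike-in sites are
    reported separately as allele fractions and never pollute the error
    summaries.  Fold changes are ``rate_a / rate_b``; when suppression
    empties the numerator count in ``b`` the fold is reported as a
    lower bound against a half-count pseudo-rate (flagged ``fold_is_bound``)
    and never enters the medians, which stay pseudocount-free.
    """
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("the two pileups share no sites")
    spike_pos = {(ref, pos): (gref, alt)
                 for ref, pos, gref, alt in (spikeins or [])}

    site_rows = []
    spike_rows = []
    for key in shared:
        sa, sb = a[key], b[key]
        if key in spike_pos:
            _gref, alt = spike_pos[key]
            af_a = sa.count(alt) / sa.depth if sa.depth else nan
            af_b = sb.count(alt) / sb.depth if sb.depth else nan
            sd = (np.sqrt(af_a * (1 - af_a) / sb.depth)
                  if sb.depth and 0 < af_a < 1 else nan)
            spike_rows.append({
                "ref_name": key[0], "pos": key[1], "alt": alt,
                "af_a": af_a, "af_b": af_b, "delta": af_b - af_a,
                "binomial_sd": sd,
                "depth_a": sa.depth, "depth_b": sb.depth,
            })
            continue
        if not (sa.callable and sb.callable) or sa.dominant != sb.dominant:
            continue
        for rec_a in site_oer_records(sa):
            m = rec_a.substitution.split(">")[1]
            rate_a = rec_a.rate
            rate_b = sb.count(m) / sb.depth
            if rate_a == 0 and rate_b == 0:
                fold, bound = 1.0, False
            elif rate_b > 0:
                fold, bound = rate_a / rate_b, False
            else:
                fold, bound = rate_a / (0.5 / sb.depth), True
            site_rows.append({
                "ref_name": key[0], "pos": key[1],
                "substitution": rec_a.substitution,
                "class": rec_a.paired_type,
                "rate_a": rate_a, "rate_b": rate_b,
                "fold_change": fold, "fold_is_bound": bound,
            })

    sites_df = pd.DataFrame(site_rows, columns=[
        "ref_name", "pos", "substitution", "class", "rate_a", "rate_b",
        "fold_change", "fold_is_bound"])
    summary_rows = []
    for cls in SUBSTITUTION_CLASSES:
        sub = sites_df[sites_df["class"] == cls]
        if len(sub) == 0:
            summary_rows.append({"class": cls, "n_sites": 0, "median_a": nan,
                                 "median_b": nan, "frac_fold_gt2": nan,
                                 "max_fold": nan, "p_value": nan})
            continue
        exact = sub[~sub["fold_is_bound"]]
        p = stats.ranksums(sub["rate_a"], sub["rate_b"]).pvalue \
            if len(sub) else nan
        summary_rows.append({
            "class": cls,
            "n_sites": int(len(sub)),
            "median_a": float(sub["rate_a"].median()),
            "median_b": float(sub["rate_b"].median()),
            "frac_fold_gt2": float((sub["fold_change"] > 2).mean()),
            "max_fold": float(sub["fold_change"].max()),
            "p_value": float(p),
        })
    summary = pd.DataFrame(summary_rows, columns=[
        "class", "n_sites", "median_a", "median_b", "frac_fold_gt2",
        "max_fold", "p_value"])
    spikes = pd.DataFrame(spike_rows, columns=[
        "ref_name", "pos", "alt", "af_a", "af_b", "delta", "binomial_sd",
        "depth_a", "depth_b"])
    return CompareResult(summary=summary, sites=sites_df, spikeins=spikes)


# ---------------------------------------------------------------------- I/O

_SITE_COLUMNS = ["ref_name", "pos", "ref", "dominant", "depth",
                 "A", "C", "G", "T", "dominant_fraction", "callable",
                 "rate_1", "rate_2", "rate_3", "sub_1", "sub_2", "sub_3"]


def write_sites(sites: Mapping, path) -> None:
    """Per-site TSV: counts, genotype call and the three substitution rates."""
    rows = []
    for (ref, pos), site in sorted(sites.items()):
        row = {
            "ref_name": ref, "pos": pos, "ref": site.ref_allele,
            "dominant": site.dominant, "depth": site.depth,
            "A": site.counts[0], "C": site.counts[1],
            "G": site.counts[2], "T": site.counts[3],
            "dominant_fraction": site.dominant_fraction,
            "callable": site.callable,
        }
        if site.callable:
            for i, rec in enumerate(site_oer_records(site), start=1):
                row[f"rate_{i}"] = rec.rate
                row[f"sub_{i}"] = rec.substitution
        rows.append(row)
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites(path, min_depth: int = 10,
               min_dominant_fraction: float = 0.95) -> dict:
    """Rebuild the site dict from a per-site TSV written by :func:`write_sites`."""
    df = pd.read_csv(path, sep="\t", dtype={"ref_name": str})
    sites = {}
    for rec in df.itertuples(index=False):
        counts = np.array([rec.A, rec.C, rec.G, rec.T], dtype=np.int64)
        site = _make_site(rec.ref_name, int(rec.pos), str(rec.ref), counts,
                          min_depth, min_dominant_fraction)
        sites[(rec.ref_name, int(rec.pos))] = site
    return sites
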