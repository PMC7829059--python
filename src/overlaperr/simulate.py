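"""Synthetic paired-end runs with a controlled error architecture.

The generator emulates the parts of real data this package measures, and
nothing else: Illumina-style read names tying each pair to a lane/tile,
per-tile *sequencer* errors drawn independently for each mate at each
cycle, *shared* (pre-sequencer: PCR or true-mutation) substitutions planted
once per fragment and copied into both mates, and low-fraction spike-in
variants applied at the fragment level.  Shared events are concordant
between mates by construction, so they raise the pileup (overall) error
rate without touching the overlap-discordance (sequencer) rate — the
separation the estimator exists to exploit.

Reads are emitted pre-aligned with single-match-run CIGARs against a
seeded random reference; a fixed seed reproduces the SAM byte for byte.
Every planted event is recorded in a truth table so tests can check
parameter recovery against the exact closed form: with per-base error
probability ``p`` in each mate, a doubly-read position is discordant with
probability ``d = 2 p (1 - p) + (2/3) p**2`` (one mate errs, or both err
to different bases), so the expected discordance rate per sequenced base
is ``d / 2 = p (1 - p) + p**2 / 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .illumina import FlowcellLayout

__all__ = ["Spikein", "SimConfig", "SimOutput", "simulate_run", "corrupt_names",
           "expected_discordance_rate", "simulated_reference"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def expected_discordance_rate(p: float) -> float:
    """Expected discordant fraction per *sequenced base* (i.e. the expected
    measured rate) when each mate errs per base with probability ``p``."""
    return p * (1.0 - p) + p * p / 3.0


@dataclass(frozen=True, slots=True)
class Spikein:
    """A known variant planted at fragment level: 1-based position, alternate
    base, allele fraction."""

    pos: int
    alt: str
    allele_fraction: float


@dataclass
class SimConfig:
    """Study conditions for one synthetic flow cell.

    ``tile_error_rates`` maps a raw tile number (or ``(lane, tile)``) to the
    per-base, per-mate sequencer error probability of that tile.  The
    defaults model a short-insert amplicon library on a well-behaved
    instrument: 100-cycle mates whose inserts (120-150 bp) always overlap,
    constant Q37 base qualities so quality filters are inert unless a test
    configures otherwise, and MAPQ 60 alignments.
    """

    reference_length: int = 400
    read_length: int = 100
    insert_range: tuple[int, int] = (120, 150)
    pairs_per_tile: int = 2000
    layout: FlowcellLayout = field(default_factory=FlowcellLayout.novaseq)
    tile_error_rates: dict = field(default_factory=lambda: {1101: 5e-6})
    shared_error_rate: float = 0.0
    spikeins: list[Spikein] = field(default_factory=list)
    phred: int = 37
    mapq: int = 60
    instrument: str = "SIM001"
    run: int = 1
    flowcell: str = "SIMFC001"
    ref_name: str = "amplicon1"
    substitution_bias: np.ndarray | None = None  # 4x4 row-stochastic, diag 0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.insert_range
        if not (self.read_length <= lo <= hi):
            raise ValueError("need read_length <= insert_min <= insert_max")
        if lo >= 2 * self.read_length:
            raise ValueError(
                "insert_min must be < 2*read_length so mates always overlap")
        if hi > self.reference_length:
            raise ValueError("insert_max exceeds the reference length")
        for p in self.tile_error_rates.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("tile error rates must be probabilities")
        if not 0.0 <= self.shared_error_rate <= 1.0:
            raise ValueError("shared_error_rate must be a probability")
        for sp in self.spikeins:
            if not (1 <= sp.pos <= self.reference_length):
                raise ValueError(f"spike-in position {sp.pos} outside reference")
            if not 0.0 <= sp.allele_fraction <= 1.0:
                raise ValueError("spike-in allele fraction must be a probability")


@dataclass
class SimOutput:
    sam: Path
    reference: Path
    truth_tiles: pd.DataFrame
    truth_events: pd.DataFrame
    truth_spikeins: pd.DataFrame

    def write_truth(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        paths = {}
        for name, df in (("tiles", self.truth_tiles), ("events", self.truth_events),
                         ("spikeins", self.truth_spikeins)):
            p = directory / f"truth_{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[name] = p
        return paths


def simulated_reference(cfg: SimConfig) -> str:
    """The reference sequence a given config/seed will generate.

    The reference is the first draw from the seeded generator, so it can be
    predicted without running the full simulation — useful for choosing
    spike-in alternate bases that differ from the reference.
    """
    rng = np.random.default_rng(cfg.seed)
    return _BASES[rng.integers(0, 4, size=cfg.reference_length)].tobytes().decode()


def _substitute(rng, current: np.ndarray, bias: np.ndarray | None) -> np.ndarray:
    """Replacement bases for the given current bases (never the same base)."""
    current_idx = np.searchsorted(_BASES, current)
    if bias is None:
        # uniform among the 3 alternatives
        offset = rng.integers(1, 4, size=len(current))
        return _BASES[(current_idx + offset) % 4]
    out = np.empty(len(current), dtype=np.uint8)
    for i, ci in enumerate(current_idx):
        out[i] = _BASES[rng.choice(4, p=bias[ci])]
    return out


def _complement(arr: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        table[a] = b
    return table[arr]


def simulate_run(cfg: SimConfig, out_dir) -> SimOutput:
    """Write ``reference.fa``, ``reads.sam`` and truth tables under ``out_dir``.

    Pairs are emitted tile by tile (tiles in sorted order) with names
    ``instrument:run:flowcell:lane:tile:x:y``; the forward mate aligns to
    the forward strand (flag 99) and the reverse mate to the reverse strand
    (flag 147), both with ``<read_length>M`` CIGARs.  Sequencer errors on
    the reverse mate are drawn per sequencing cycle: cycle ``c`` of the
    reverse mate is query position ``read_length - c`` in reference
    orientation, and with a substitution bias configured the error is
    applied on the sequenced (complement) strand.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    L, RL = cfg.reference_length, cfg.read_length
    ref = _BASES[rng.integers(0, 4, size=L)]

    ref_path = out_dir / "reference.fa"
    with open(ref_path, "w") as fh:
        fh.write(f">{cfg.ref_name}\n")
        seq = ref.tobytes().decode()
        for i in range(0, L, 60):
            fh.write(seq[i: i + 60] + "\n")

    sam_path = out_dir / "reads.sam"
    qual_str = chr(cfg.phred + 33) * RL
    cigar = f"{RL}M"
    events = []
    tile_rows = []
    spike_cov = np.zeros(len(cfg.spikeins), dtype=np.int64)
    spike_carry = np.zeros(len(cfg.spikeins), dtype=np.int64)
    alt_idx = {sp.pos: np.frombuffer(sp.alt.encode(), np.uint8)[0]
               for sp in cfg.spikeins}

    def tile_key(k):
        return (k[0], k[1]) if isinstance(k, tuple) else (1, int(k))

    with open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unsorted\n")
        sam.write(f"@SQ\tSN:{cfg.ref_name}\tLN:{L}\n")
        sam.write("@PG\tID:overlaperr-simulate\tPN:overlaperr\n")
        for raw_key in sorted(cfg.tile_error_rates, key=tile_key):
            lane, tile = tile_key(raw_key)
            p = cfg.tile_error_rates[raw_key]
            n = cfg.pairs_per_tile
            starts = rng.integers(0, L - cfg.insert_range[1] + 1, size=n)
            inserts = rng.integers(cfg.insert_range[0], cfg.insert_range[1] + 1,
                                   size=n)
            k_shared = (rng.binomial(inserts, cfg.shared_error_rate)
                        if cfg.shared_error_rate > 0 else np.zeros(n, np.int64))
            k_fwd = rng.binomial(RL, p, size=n) if p > 0 else np.zeros(n, np.int64)
            k_rev = rng.binomial(RL, p, size=n) if p > 0 else np.zeros(n, np.int64)
            carriers = []
            for j, sp in enumerate(cfg.spikeins):
                pos0 = sp.pos - 1
                covered = (starts <= pos0) & (pos0 < starts + inserts)
                take = covered & (rng.random(n) < sp.allele_fraction)
                spike_cov[j] += int(covered.sum())
                spike_carry[j] += int(take.sum())
                carriers.append(take)
            seq_err_f = seq_err_r = 0
            shared_total = 0
            for i in range(n):
                s = int(starts[i])
                ins = int(inserts[i])
                frag = ref[s: s + ins].copy()
                name = (f"{cfg.instrument}:{cfg.run}:{cfg.flowcell}:"
                        f"{lane}:{tile}:{1000 + i}:{1000 + tile}")
                for j, sp in enumerate(cfg.spikeins):
                    if carriers[j][i]:
                        frag[sp.pos - 1 - s] = alt_idx[sp.pos]
                        events.append((name, "spikein", sp.pos, 0,
                                       chr(ref[sp.pos - 1]), sp.alt))
                if k_shared[i]:
                    pos = rng.choice(ins, size=int(k_shared[i]), replace=False)
                    old = frag[pos].copy()
                    frag[pos] = _substitute(rng, old, None)
                    shared_total += int(k_shared[i])
                    for q, o in zip(pos, old):
                        events.append((name, "shared", s + int(q) + 1, 0,
                                       chr(o), chr(frag[q])))
                fwd = frag[:RL]
                rev = frag[ins - RL:]
                if k_fwd[i] or k_rev[i]:
                    fwd = fwd.copy()
                    rev = rev.copy()
                    if k_fwd[i]:
                        cyc = rng.choice(RL, size=int(k_fwd[i]), replace=False) + 1
                        idx = cyc - 1
                        old = fwd[idx].copy()
                        fwd[idx] = _substitute(rng, old, cfg.substitution_bias)
                        seq_err_f += int(k_fwd[i])
                        for c, o, q in zip(cyc, old, idx):
                            events.append((name, "sequencer_fwd", s + int(q) + 1,
                                           int(c), chr(o), chr(fwd[q])))
                    if k_rev[i]:
                        cyc = rng.choice(RL, size=int(k_rev[i]), replace=False) + 1
                        idx = RL - cyc
                        old = rev[idx].copy()
                        if cfg.substitution_bias is None:
                            rev[idx] = _substitute(rng, old, None)
                        else:
                            # bias acts on the sequenced (complement) strand
                            rev[idx] = _complement(
                                _substitute(rng, _complement(old),
                                            cfg.substitution_bias))
                        seq_err_r += int(k_rev[i])
                        rev_start = s + ins - RL
                        for c, o, q in zip(cyc, old, idx):
                            events.append((name, "sequencer_rev",
                                           rev_start + int(q) + 1, int(c),
                                           chr(o), chr(rev[q])))
                fwd_pos = s + 1
                rev_pos = s + ins - RL + 1
                sam.write(
                    f"{name}\t99\t{cfg.ref_name}\t{fwd_pos}\t{cfg.mapq}\t{cigar}"
                    f"\t=\t{rev_pos}\t{ins}\t{fwd.tobytes().decode()}\t{qual_str}\n")
                sam.write(
                    f"{name}\t147\t{cfg.ref_name}\t{rev_pos}\t{cfg.mapq}\t{cigar}"
                    f"\t=\t{fwd_pos}\t{-ins}\t{rev.tobytes().decode()}\t{qual_str}\n")
            tile_rows.append({
                "lane": lane,
                "tile": tile,
                "per_base_error_rate": p,
                "expected_ser_pm": expected_discordance_rate(p) * 1e6,
                "pairs": n,
                "sequencer_errors_fwd": seq_err_f,
                "sequencer_errors_rev": seq_err_r,
                "shared_errors": shared_total,
            })

    truth_tiles = pd.DataFrame(tile_rows, columns=[
        "lane", "tile", "per_base_error_rate", "expected_ser_pm", "pairs",
        "sequencer_errors_fwd", "sequencer_errors_rev", "shared_errors"])
    truth_events = pd.DataFrame(events, columns=[
        "read_name", "kind", "pos", "cycle", "from_base", "to_base"])
    truth_spikeins = pd.DataFrame({
        "pos": [sp.pos for sp in cfg.spikeins],
        "alt": [sp.alt for sp in cfg.spikeins],
        "allele_fraction": [sp.allele_fraction for sp in cfg.spikeins],
        "covering_fragments": spike_cov,
        "carrier_fragments": spike_carry,
    })
    return SimOutput(sam=sam_path, reference=ref_path, truth_tiles=truth_tiles,
                     truth_events=truth_events, truth_spikeins=truth_spikeins)


def corrupt_names(sam_in, sam_out, mode: str = "sra_strip") -> int:
    """Rewrite read names into an archive-mangled dialect, for negative paths.

    ``sra_strip`` replaces each distinct name with ``SRR000001.<serial>``
    (mates keep a common name, so pairing still works but location parsing
    cannot); ``truncate`` drops the final ':'-field.  Returns the number of
    records rewritten.
    """
    if mode not in ("sra_strip", "truncate"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    seen: dict[str, str] = {}
    n = 0
    with open(sam_in) as src, open(sam_out, "w") as dst:
        for line in src:
            if line.startswith("@"):
                dst.write(line)
                continue
            name, rest = line.split("\t", 1)
            if mode == "sra_strip":
                new = seen.get(name)
                if new is None:
                    new = f"SRR000001.{len(seen) + 1}"
                    seen[name] = new
            else:
                new = name.rsplit(":", 1)[0]
            dst.write(f"{new}\t{rest}")
            n += 1
    return n
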