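# Methods

## Model

A paired-end read pair whose insert is shorter than twice the read length
reads the middle of the fragment twice. Pre-sequencer events — somatic
mutations in the cell population, polymerase misincorporations during
library amplification — are properties of the fragment and appear
identically in both mates; instrument miscalls are drawn independently per
mate per cycle. Within the overlap, a position where the two mates
disagree is therefore attributable to the instrument. The sequencer error
rate (sER) of an evaluation unit is the ratio of discordant positions to
sequenced bases over its read pairs,

    e = sum_r m_r / sum_r 2 n_r,

where `n_r` counts included overlap positions of pair `r` (each sequenced
twice, hence the factor 2) and `m_r` counts the discordant ones. Units
follow the physical nesting of an Illumina run — tile ⊂ swath ⊂ lane ⊂
surface ⊂ flow cell ⊂ instrument — recovered from the 7-field read name;
the same ratio per sequencing cycle gives a per-cycle profile for each
mate. Lane-level rates are computed and reported but never drive outlier
decisions, since lane assignment is a library-pooling choice rather than
an instrument property.

The complementary measurement is the site-specific overall error rate
(oER) from a deep pileup: at a site whose post-filter depth exceeds 10 and
whose dominant allele holds more than 95% of reads, the rate of each of
the three mismatch bases is its read count over the site depth. The
dominant (called) allele — not the reference FASTA base — plays the
wild-type role, because at these depths the observed majority is the
stronger genotype evidence; the FASTA anchors coordinates and reporting.
oER mixes all error sources, so the sER/oER pair separates instrument
contributions from library contributions: shared errors raise oER but
leave sER untouched.

Under the model, if each mate miscalls a given position with probability
`p`, a doubly-read position is discordant when exactly one mate errs or
both err to different bases:

    d = 2 p (1 - p) + (2/3) p^2,

(the 2/3 because two independent uniform choices among the three
alternative bases collide with probability 1/3), so the expected measured
rate per sequenced base is `d / 2 = p (1 - p) + p^2 / 3 ≈ p` for small
`p`. Tests and the acceptance studies use this exact closed form with a
`3 sqrt(d (1 - d) / (2 B))` binomial tolerance at `B` sequenced bases.

## Quality gate

Six rules precede all counting, evaluated in a fixed order so verdicts are
deterministic and the first failing reason is reported:

| rule | default | rationale |
|---|---|---|
| mapped, primary, proper pair | required | unique, expected-orientation alignments only |
| MAPQ | 55–254 | excludes ambiguous placements; 255 ("unavailable") rejected |
| CIGAR | `^\d+M$` | a single match run maps cycles linearly to reference positions; indel-bearing reads are excluded rather than modeled |
| low-quality fraction | < 5% of bases below Q20, on the full read before trimming | whole-read quality screen |
| per-base threshold | Phred ≥ 30, no N | an N is a no-call, not a discordance |
| end trim | first 5 cycles of each mate | known quality drop at the start of reads |

"First five cycles" is interpreted in sequencing order: cycle 1 is the 5'
end of the raw read, which for a reverse-strand alignment is the last
stored base. A position enters the overlap tally only when the base from
*each* mate passes the per-base rules; a half-passing position contributes
to neither numerator nor denominator, since concordance cannot be checked
from one base. Duplicate-marked reads are included by default (amplicon
deep sequencing is duplicate-dominated) with a flag to exclude; QC-fail,
secondary and supplementary records are always excluded. Relaxing every
threshold (`FilterConfig.relaxed()`, `--no-suppression`) reproduces the
unfiltered measurement mode; structural rules (mapped, proper, simple
CIGAR) still apply because the overlap is undefined without them.

## Stratified aggregation and outliers

Integer counts (mismatches, bases, pairs) are the interchange format;
rates are always derived downstream, so pooling runs, flow cells or
instruments is exact, and tile sums reconcile with surface and flow-cell
totals as an asserted integer identity. Tile strata are keyed
`(flowcell, lane, tile)` because raw tile numbers repeat across lanes.
Surfaces come from the tile number's digit code, configurable per
platform: 4-digit surface/swath/position ("SWPP", e.g. tile 2159 = bottom
surface, swath 1, position 59) for HiSeq/NovaSeq-style numbering, 5-digit
surface/swath/camera/position ("SWCPP") for NextSeq-style, overridable via
a layout YAML so vendor layout drift never invalidates the counting.

Sufficiency gates keep noise out of summaries: 2,000,000 sequenced bases
at flow-cell (and lane) level and 1,000,000 at surface level. No
tile-level minimum is established in the field; the default here is
100,000 — roughly a tile's share of the surface minimum on a 10–20-tile
surface. Insufficient strata are flagged and excluded from outlier
statistics, never reported as zero-rate; zero-base strata report NaN, not
0. The stated minimums count sequenced bases (2 per overlap position); a
`min_bases_unit="positions"` switch gates on positions instead, for the
reading under which "overlapping base pairs" means positions.

A sufficient stratum with sER > 100 pm is an outlier (strict inequality).
Surface comparison reports each surface's rate and its outlier-tile
fraction, flagging surfaces above a configurable 10% load.

## Suppression

Suppression removes reads, never modifies bases. Outlier sets are keyed
by (flowcell, tile) — matching a tile number in any lane — with
whole-surface wildcards expanded through the tile decoder. Both mates of
a pair share a read name and therefore a tile, so pair integrity is
automatic, and re-suppressing with the same set is a record-level no-op.
Reads with unparseable names are kept by default: suppression must be
conservative, and a mangled name is no evidence against the read.

## Comparison of pileups

`compare_runs` takes a baseline and a comparison pileup over the same
sites. The 12 substitutions collapse into 6 complementary-strand classes
(A>C/T>G, …); per class it reports both arms' median rates, the fraction
of sites with more than 2-fold reduction, the maximum fold change, and a
two-sided Wilcoxon rank-sum p-value. A site whose mismatch count drops to
zero in the comparison arm gets a fold-change *bound* against a half-count
pseudo-rate, flagged as such and used only for ranking and the >2-fold
tally — medians stay pseudocount-free. Spike-in sites (known variants
supplied as a TSV) are diverted to a separate allele-fraction report with
a binomial-SD yardstick and never enter the error summaries.

## Synthetic data

The generator emulates exactly the features the estimators read: 7-field
Illumina names with configurable lane/tile placement; per-tile binomial
sequencer errors drawn independently per mate per cycle; shared
(pre-sequencer) substitutions drawn once per fragment and copied into both
mates; spike-in variants assigned per fragment at a stated allele
fraction; constant Q37 qualities (so quality filters are inert unless a
test configures otherwise) and MAPQ 60, pre-aligned simple-CIGAR records
against a seeded random reference. Substitutions are uniform among the
three alternatives by default, with an optional 4×4 bias matrix applied on
the sequenced strand to exercise per-substitution reporting. Every
planted event lands in a truth table, and a fixed seed reproduces the SAM
byte for byte.

It deliberately omits quality-score evolution, indel errors, optical
duplicates, alignment ambiguity and reference bias. Passing tests
therefore demonstrate correct counting, stratification, detection and
suppression under the stated error model — not robustness to alignment
artifacts, which real data must handle through the upstream aligner and
the quality gate.

Default study conditions used by the test suite and the acceptance
script: 100-cycle mates, inserts 110–150 bp (always-overlapping, as in
short-insert amplicon libraries), per-base rates 5×10⁻⁶ for ordinary
tiles (≈ 5 pm, the order observed on healthy instruments) against
5×10⁻⁴ planted outliers (well past the 100 pm threshold), shared errors
at 50 pm (between polymerase and somatic-mutation scales), spike-ins at
0.1%. The parameter-recovery study uses 21 tiles × 68,000 pairs
(> 10⁷ included bases per tile, where the 3-SD band around 5 pm is
±2.1 pm); pileup studies use 250–300 bp references at ~15,000× depth so
binomial expectations are sharp at desk scale.

## Numerical and design choices

- Overlap is the intersection of the mates' reference spans (valid because
  only single-match-run alignments pass); no sequence-based
  re-overlapping, which would re-introduce alignment artifacts.
- Coordinates are 0-based half-open internally; all emitted site
  coordinates are 1-based (SAM/VCF convention).
- Discordance is binary per position; since which mate erred is
  unknowable, a discordance charges both mates' cycle strata, and each
  included position contributes one base to each mate's cycle series (so
  forward and reverse profiles are separate).
- Mate pairing is by read name with a bounded buffer (coordinate- or
  name-sorted input both work); exceeding the buffer raises an error
  advising name collation rather than silently spilling.
- The low-quality-fraction rule is evaluated on the full read before end
  trimming (the rule screens overall read quality, not the analyzed
  subset).
- Pileup depth is post-filter depth, consistent with the gate applying to
  every measurement; overlapping mates both count, as in standard deep
  pileups.
- Dominant-allele ties break in A<C<G<T order; ties can never satisfy the
  > 95% dominance rule, so the tie-break never decides callability.
- No per-pair minimum overlap length is imposed; zero-overlap pairs pass
  through contributing nothing.
- Grid exports place every decodable tile in exactly one cell, with
  missing data as NaN (never zero); the 200 pm display cap exists only in
  plotting code.

## Limitations

- Requires overlapping mates: long-insert libraries (typical WGS) carry
  little signal; an internal standard of short fragments is the practical
  workaround.
- Requires original Illumina read names; archive-reformatted datasets
  (accession-style names) are detected, tallied and refused rather than
  mis-stratified.
- Requires a reference for the alignment step that produces the input;
  alignment itself is out of scope.
- Tile-level suppression is the finest grain offered; read- or
  cycle-level suppression is a possible refinement, not implemented.
- Indel discordances are not measured (indel-bearing reads are excluded
  upstream by the CIGAR rule); no base correction or error-model fitting
  is performed.
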