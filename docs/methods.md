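# Methods

## Scope and model

`tandemtriage` analyzes targeted long-read sequencing of tandem-repeat
(TR) disease loci. The underlying measurement model is that a long read
which fully spans a repeat tract, with uniquely alignable flank on both
sides, carries the allele's complete repeat content; the aligner encodes
any length difference from the reference as insertions/deletions in or
adjacent to the tract. Repeat length change is therefore read off the
CIGAR rather than re-assembled. Everything downstream — genotyping,
prioritization, decomposition, triage — consumes these per-read
measurements.

## Locus catalog

Each locus carries 0-based half-open reference tract coordinates, ordered
motif sets (pathogenic first — the order is a tie-break priority in
decomposition), the reference unit count, optional clinical unit-count
thresholds, and an inheritance mode. The shipped catalog has 13 loci: 12
classic repeat-disease loci (HTT, ATXN3, CACNA1A, DMPK, ATXN8OS,
NOTCH2NLC, PHOX2B, SAMD12, RFC1 — with the ACAGG variant motif folded into
its pathogenic set — BEAN1, NOP56, CSTB) plus the polymorphic TNRC6A
pentanucleotide locus, and the SCA31-linked SNP as a 40-kb SNP target.
Thresholds are standard clinical values; TNRC6A ships null thresholds
deliberately: a missing threshold always yields an *undetermined* triage
verdict rather than a guessed one.

The reference tract motif (`ref_motif`) is the first benign motif where
one is catalogued (AAAAG at RFC1, TTTTA at SAMD12/TNRC6A, TAAAA at BEAN1 —
normal alleles at these loci carry the benign unit, and a pathogenic-motif
reference would make reference-length alleles triage as pathogenic), else
the primary pathogenic motif.

Target design: the adaptive-sampling BED places one window of **total**
width `window_bp` (default 100 kb) centered on each tract. A 59-locus
panel plus the 40-kb SNP window then covers 0.2% of GRCh38, matching the
production design; a `flank` mode padding each side is available for the
alternative reading of "surrounding 100 kb".

## Simulator

The simulator defines the study conditions under which everything is
tested:

- **Mini-genome**: per locus one contig of seeded-random flank (default
  8 kb) + `ref_units × ref_motif` + flank; per SNP target a contig with
  the reference base at its center. The catalog is rebased onto these
  contigs.
- **Alleles**: ordered motif compositions, e.g.
  `(TTTCA)×167 + (TTTTA)×500`. Unspecified loci are homozygous reference.
- **Reads**: each allele contributes `round(depth/2)` tract-spanning reads
  (start uniform over valid positions; 20× total by default) plus 25%
  flank-only reads that exercise the spanning filter and off-tract
  coverage. Lengths are lognormal (mean 20 kb, σ 0.5, truncated to
  2–100 kb; DNA for such runs is sheared to tens of kb), clamped so a
  spanning read always has ≥400 bp beyond the tract. Strand is uniform.
- **Errors**: per-base substitution 1%, insertion 0.5%, deletion 0.5%
  (the order of magnitude of raw nanopore read accuracy in the mid-90s%),
  applied to an exact aligned-pairs edit script so the emitted SAM CIGAR
  is the true alignment. No aligner runs anywhere in the test path.
- **Motif miscall artifact**: optionally, whole source-motif units on one
  strand are corrupted (default use: AAGGG→AAGG at 0.3/unit on the minus
  strand). The per-unit rate is a visibility calibration, not an estimate:
  the artifact's real rate is not quantified, only its strand specificity
  and identity.
- **Controls**: per control and locus, two allele unit counts uniform in
  `ref_units ± jitter` (default 27 controls, jitter 3 → 54 alleles per
  locus). Real control cohorts have locus-specific allele spectra; the
  uniform jitter models only what prioritization consumes — a bounded
  normal-range copy-change distribution.
- **Methylation**: per read of a profiled locus, each CpG emits a
  probability from a beta distribution with mean equal to the allele's
  methylation level (concentration 10); profiles ≤0.01 / ≥0.99 draw from
  narrow uniform bands so fully (un)methylated alleles stay clean.

What the simulator does **not** emulate: pore-level signal, realistic
quality strings, context-dependent error hotspots, mosaicism, chimeras,
segmental-duplication mismapping, or adaptive-sampling rejection dynamics.
Passing tests therefore demonstrate correctness of the measurement,
clustering, ranking and triage logic under a clean but realistically
noisy error model — not robustness to every failure mode of real flow
cells.

## Genotyper

`Δbp` sums insertion lengths whose reference anchor lies within one motif
length of the tract (aligners place tract insertions at either boundary)
minus deletion overlap with the tract itself. `Δu = round(Δbp / motif_len)`
with ties toward zero, so 1–2 bp of alignment jitter keeps unexpanded
reads at exactly 0. Spanning requires 100 bp of aligned flank on both
sides (`anchor_bp`, configurable); non-spanning reads are measured but
excluded from genotyping. Minimum mapping quality defaults to 1 because
targeted panels include segmentally duplicated loci where unique mapping
quality is depressed.

Genotyping enumerates all n−1 contiguous splits of the sorted `Δu` values
and takes the split minimizing within-cluster sum of squares — exact for
1-D, deterministic, and directly checkable against enumeration of all
2-partitions (the optimum is always contiguous in 1-D). Cluster medians
give the allele copy changes; centers closer than `max(2, 0.1 × larger)`
collapse to a homozygous call at the overall median. Fewer than
`min_support` (default 3) spanning reads → undetermined.

## Prioritizer

`score = (patient_stat − control_max) × motif_len`, ranked descending,
ties broken by genomic position; loci with insufficient spanning support
rank last with a −∞ sentinel and a flag. The m-th-largest patient
statistic (`m = max(2, ⌈0.1 n⌉)`) discards single aberrant reads. The
bp-scaling deliberately lets a multi-hundred-unit pentanucleotide
polymorphism outrank a 20-unit trinucleotide disease expansion — the
ranking is a search order, not a verdict; judging pathogenicity is the
evaluator's job. The control summary is the maximum (not a quantile): with
27 controls, any patient change beyond every control is notable. The
score formula is this package's own; the upstream workflow it mirrors
delegates ranking to an external tool whose exact criterion is not
published.

## Decomposer

Consensus is the medoid read (minimum summed edit distance, edlib NW)
polished by per-column majority over global pairwise alignments; ties
keep the medoid base, majority-gap columns are dropped, insertions
relative to the medoid are ignored. This is deliberately not an
assembler: it is deterministic, linear in reads, and sufficient for unit
counting; its known bias is losing a few units when indel errors dominate
(a 622-unit simulated tract polishes to ~619 units at default error
rates).

Decomposition minimizes cost 1 per OTHER base, 0 per exact unit, 1 per
mismatched base inside a unit — mismatch tolerance (default 1/unit)
applies only to motifs of length ≥ 4, because a 1-mismatch trinucleotide
matches almost anything. Equal-cost segmentations prefer fewer OTHER runs,
then earlier-listed motifs (pathogenic motifs are listed first, so TGGAA
beats TAGAA where both fit). The DP is verified against exhaustive
enumeration of all segmentations on short sequences. Interruption calls
are maximal runs of non-pathogenic motif units positioned 5'/internal/3'
relative to the pathogenic block.

## Evaluator

Rules, in order, on the larger allele's pathogenic-motif unit count
(from the decomposition when available, else the total unit count flagged
`composition_unverified`):

- **R1** count ≥ pathogenic_min → **R3** inheritance: AR with the smaller
  allele also ≥ min → pathogenic; AR otherwise → carrier; AD/XL →
  pathogenic.
- **R2** total units ≥ pathogenic_min but pathogenic-motif units ≤
  normal_max → benign_polymorphic (a long benign-motif tract, e.g.
  TAAAA/TAGAA at the SCA31 locus).
- **R4** otherwise: count > normal_max → intermediate, else
  benign_polymorphic.

The SCA8 locus ships `normal_max = 40` for the pure-CTG count — a
conservative judgment placing the mid-40s CTG range in the intermediate
band, consistent with treating such alleles as unlikely pathogenic — with
the accepted pathogenic minimum of 71. Linked-SNP genotypes (pileup,
≥20% minor-allele fraction) are reported alongside but never alter a
verdict: a negative linked SNP cannot exclude the diagnosis.

## Methylation

Allele labels: hypermethylated if the fraction of (read, CpG)
observations with probability ≥ 0.5 is ≥ 0.6, unmethylated if ≤ 0.2, else
partial; < 10 observations → no-call. The 0.6/0.2/10 values are this
package's operating points for a qualitatively described hyper/unmethylated
distinction, and are configurable. Reads are assigned to alleles via the
genotyper's supporting-read partition.

## QC

Reads ≤ 1000 bp are excluded before any depth computation (adaptive
sampling ejects non-target molecules early, so very short reads are
rejects). On-target depth is the mean of per-locus window means;
off-target coverage is tiled in 5-kb bins over everything else, and
zero-coverage bins count toward the off-target average (making it a
genome-wide mean; configurable). An infinite enrichment ratio (no
off-target coverage at all, the usual case on a mini-genome) serializes
as the string `"inf"`. Down-sampling is exact sampling without
replacement, deterministic per seed. Carryover for serial samples on one
flow cell is simply `previous_depth × residual_fraction` (0.001 for a
99.9%-effective wash).

## Validation simulation and problem sizes

`run_validation_cohort` simulates twelve confirmed genotypes (one per
classic locus, including biallelic SCA8, the benign-plus-pathogenic
pentanucleotide composition at SAMD12, and homozygous RFC1) on the
13-locus mini-genome at 20× spanning depth with default errors, adds the
two confounders observed in practice (a large benign TTTTA expansion at
TNRC6A alongside a small CACNA1A expansion; a heterozygous RFC1 expansion
alongside a DMPK expansion), and prioritizes each patient against 27
simulated controls. The causal locus ranks first in 10/12 and second —
behind exactly those confounders — in 2/12, reproducing the expected
rank-1 rate of 83.3% and top-2 rate of 100%. One cohort run is ~20 s on
one CPU; unit tests use single-locus catalogs (seconds) and the
20-seed recovery suites use one locus at 20×.

## Numerical and degenerate-input choices

- Rounding is half-toward-zero everywhere unit counts are derived from bp.
- Genotype split ties take the first minimal split; all orderings are
  explicit (read id, genomic position) so every output is deterministic.
- Zero spanning reads at requested depth is a warning in the truth table,
  not an error; an empty BED, an empty control table, empty consensus
  input, and mixed-locus measurement sets are errors.
- Any sequence decomposes (worst case all OTHER); empty sequences yield
  empty decompositions.

## Known limitations

- Copy-change measurement trusts the aligner's indel placement; split or
  chimeric alignments are skipped, not rescued.
- The consensus underestimates very long tracts by a few units under
  indel-heavy error models; unit counts for threshold decisions should be
  read from the genotyper (length-based), with decomposition supplying
  motif identity — which is exactly how the evaluator combines them.
- The two-cluster genotyper assumes a diploid sample; somatic mosaicism
  and more than two length classes are out of scope.
- Prioritization has no significance model; it is an ordering for expert
  review, and the triage rules only fire where catalog thresholds exist.
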