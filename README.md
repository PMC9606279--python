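# tandemtriage

Targeted long-read diagnostics for tandem-repeat expansion diseases.

Dozens of neurological and neuromuscular disorders — Huntington's disease,
the spinocerebellar ataxias, CANVAS, myotonic dystrophy, NIID, BAFME — are
caused by a short tandem repeat (TR) exceeding a locus-specific pathogenic
unit count. Conventional diagnostics (flanking PCR, repeat-primed PCR,
southern blotting) interrogate one locus at a time and rarely reveal the
full repeat sequence. Targeted long-read sequencing with adaptive sampling
enriches every catalogued disease locus in a single run; `tandemtriage` is
the analysis side of that workflow, for clinical genomicists and
bioinformaticians who have aligned long reads over a repeat-disease panel
and need to know *which locus is expanded, by how much, with what motif
content, and whether that is pathogenic*.

## What it computes

Given aligned long reads (SAM/BAM), a locus catalog, and a control cohort:

1. **Per-read copy-number change.** For a read spanning a repeat tract
   `[s, e)` with at least 100 bp of anchored flank on both sides,

   `Δbp = Σ len(I) for insertions anchored in [s − m, e + m] − Σ overlap(D, [s, e))`

   where `m` is the motif length; the unit change is
   `Δu = round(Δbp / m)` with ties toward zero.
2. **Two-allele genotype.** Exhaustive 1-D two-cluster split of the sorted
   per-read `Δu` minimizing within-cluster sum of squares (exact in 1-D);
   cluster medians become the allele copy changes, collapsing to a
   homozygous call when centers differ by less than `max(2, 10%)` units.
   Allele unit counts are `ref_units + Δu`.
3. **Prioritization.** Per locus, `score = (patient_stat − control_max) × m`
   where `patient_stat` is the m-th largest per-read `Δu`
   (`m = max(2, ⌈0.1 n⌉)`, robust to single chimeric reads) and
   `control_max` is the largest control-allele copy change (54 alleles from
   27 controls by default). Loci are ranked by descending bp-scale score.
4. **Motif decomposition.** A minimal-cost dynamic program labels every
   base of a consensus tract (medoid read + per-column majority polish)
   with a catalogued motif unit or OTHER — the data behind waterfall
   plots, composition counts, and interruption calls (e.g. the CAACAG
   closing an expanded CAG tract).
5. **Triage.** Rules over the larger allele's *pathogenic-motif* unit
   count: ≥ pathogenic minimum → pathogenic (or carrier at an autosomal-
   recessive locus with one expanded allele); a long tract of benign
   motifs only → benign polymorphism; between the normal maximum and the
   pathogenic minimum → intermediate; missing thresholds → undetermined,
   never a guess.
6. **Methylation & QC.** Allele-level CpG methylation classification from
   per-read 5mC probabilities (with in-silico bisulfite-like conversion),
   on/off-target coverage with enrichment ratio, read-length filtering,
   down-sampling, and serial-sample carryover estimates.

A full synthetic-data layer (`tandemtriage.simulate`) generates
mini-genomes, diploid reads with exact ground-truth CIGARs, control
cohorts, and methylation tables, so the entire pipeline runs and is tested
without any external data or aligner.

## Worked example

Simulate a CANVAS-like patient (homozygous 622-unit AAGGG expansion at
RFC1) on the shipped 13-locus catalog, then run the full pipeline against
a simulated 27-control cohort:

```
$ tandemtriage simulate --patient P09 --depth 20 --seed 4 --out sim
wrote 358 reads for P09 to sim

$ tandemtriage run --catalog sim/mini_catalog.tsv --snps sim/mini_snps.tsv \
      --bam sim/reads.sam --controls sim/controls.tsv \
      --patient-id P09 --out out
pathogenic: RFC1

$ tandemtriage report --report out/report.json
patient: P09
summary: pathogenic: RFC1
  RFC1: pathogenic (alleles [622, 622], rules R1,R3:AR-biallelic)
```

The pipeline measured every read's repeat copy change, genotyped RFC1 as
622/622 units (reference 11), ranked RFC1 first against the controls, and
the triage rules fired R1 (pathogenic-motif units ≥ 400) and
R3:AR-biallelic (both alleles expanded at a recessive locus). Decomposing
the expanded allele's consensus:

```
$ tandemtriage decompose --measurements out/measurements.tsv --locus RFC1 \
      --catalog sim/mini_catalog.tsv --out-prefix out/rfc1
consensus 3106 bp from 8 reads; composition {'AAGGG': 619, 'OTHER': 3}
```

— a ~3.1 kb tract of AAGGG units (619 of the 622 simulated; the sequencing
error model costs the consensus a few units), confirming the pathogenic
motif rather than the benign AAAAG.

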