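"""Pathogenicity triage of genotyped repeat loci.

Encodes the data-evaluation flow a diagnostician applies to the
prioritized locus list: does the larger allele carry at least the
pathogenic minimum number of *disease-linked* motif units (a long tract of
benign units — e.g. TAAAA/TAGAA at the SCA31 locus — is a polymorphism);
is the count merely intermediate between the normal maximum and the
pathogenic minimum; and, for recessive loci, are one or both alleles
expanded (carrier vs affected)?  Missing thresholds never produce a guess:
the verdict is undetermined.

Rule ids recorded in the rationale:

* ``R1``  — larger-allele pathogenic-motif units >= pathogenic_min
* ``R2``  — long tract composed of benign motifs only -> benign_polymorphic
* ``R3``  — inheritance logic (AR one allele -> carrier; AR both / AD / XL
  -> pathogenic)
* ``R4``  — sub-threshold count: intermediate vs benign_polymorphic
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
import pysam

from .catalog import RepeatLocus, SnpTarget
from .decomposer import MotifDecomposition
from .genotyper import LocusGenotype

__all__ = [
    "TriageCall",
    "TriageReport",
    "evaluate_locus",
    "adjust_fragment_units",
    "summarize_cohort",
    "genotype_snp",
    "NO_EXPANSION",
]

NO_EXPANSION = "no known repeat expansion"

VERDICTS = ("pathogenic", "benign_polymorphic", "carrier", "intermediate",
            "undetermined")


@dataclass(frozen=True)
class TriageCall:
    locus_id: str
    verdict: str
    rationale: tuple[str, ...]
    allele_units: tuple[int, int] | None
    pathogenic_motif_units: int | None
    composition_verified: bool = True


@dataclass(frozen=True)
class TriageReport:
    patient_id: str
    calls: tuple[TriageCall, ...]       # in prioritized order
    summary: str
    multiple_hits: bool = False


def _pathogenic_units(genotype: LocusGenotype,
                      composition: MotifDecomposition | None,
                      locus: RepeatLocus,
                      allele_units: int) -> tuple[int, bool]:
    """Disease-motif unit count for one allele: from the decomposition when
    available, else the total unit count (flagged composition-unverified)."""
    if composition is not None:
        return composition.units_of(locus.pathogenic_motifs), True
    return allele_units, False


def evaluate_locus(genotype: LocusGenotype,
                   composition: MotifDecomposition | None,
                   locus: RepeatLocus) -> TriageCall:
    """Apply the triage rules to one locus.

    ``composition`` should be the decomposition of the larger allele's
    consensus tract over the locus motif set; pass ``None`` when no
    decomposition was run (total unit counts are then used, flagged).
    """
    if genotype.undetermined:
        return TriageCall(locus.locus_id, "undetermined",
                          ("no-genotype",), None, None)
    if locus.pathogenic_min_units is None or locus.normal_max_units is None:
        return TriageCall(locus.locus_id, "undetermined", ("no-threshold",),
                          genotype.allele_units, None)

    units_small, units_large = genotype.allele_units
    p_units, verified = _pathogenic_units(genotype, composition, locus,
                                          units_large)
    rationale: list[str] = []
    pmin, nmax = locus.pathogenic_min_units, locus.normal_max_units

    if p_units >= pmin:
        rationale.append("R1")
        # the smaller allele's total unit count stands in for its
        # pathogenic-unit count (no per-allele decomposition of the
        # normal allele)
        small_p = units_small
        if locus.inheritance == "AR":
            if small_p >= pmin:
                rationale.append("R3:AR-biallelic")
                verdict = "pathogenic"
            else:
                rationale.append("R3:AR-monoallelic")
                verdict = "carrier"
        else:
            rationale.append(f"R3:{locus.inheritance}")
            verdict = "pathogenic"
        return TriageCall(locus.locus_id, verdict, tuple(rationale),
                          genotype.allele_units, p_units, verified)

    # below the pathogenic minimum
    if verified and units_large >= pmin and p_units <= nmax:
        # long expansion, but of benign motifs only
        return TriageCall(locus.locus_id, "benign_polymorphic",
                          ("R2",), genotype.allele_units, p_units, True)
    if p_units > nmax:
        return TriageCall(locus.locus_id, "intermediate", ("R4:intermediate",),
                          genotype.allele_units, p_units, verified)
    return TriageCall(locus.locus_id, "benign_polymorphic", ("R4:benign",),
                      genotype.allele_units, p_units, verified)


def adjust_fragment_units(total_units: tuple[int, int],
                          observed_secondary_units: int,
                          reference_secondary_units: int) -> tuple[int, int]:
    """Correct fragment-analysis unit totals for a co-amplified secondary
    repeat: subtract the observed excess of secondary units over the
    reference from each allele's total (floored at zero).  E.g. totals
    (22, 46) with 11 observed vs 9 reference CCG units -> (20, 44)."""
    if observed_secondary_units < 0 or reference_secondary_units < 0:
        raise ValueError("unit counts must be >= 0")
    if any(u < 0 for u in total_units):
        raise ValueError("unit counts must be >= 0")
    excess = observed_secondary_units - reference_secondary_units
    return tuple(max(0, u - excess) for u in total_units)


def summarize_cohort(ranked_truth: Sequence[tuple[str, int]]):
    """Validation-style summary: given per-patient (patient_id, rank of the
    known causal locus), return (fraction at rank 1, fraction within ranks
    1-2, per-patient frame)."""
    if not ranked_truth:
        raise ValueError("no reports to summarize")
    df = pd.DataFrame(ranked_truth, columns=["patient_id", "causal_rank"])
    rank1 = float((df["causal_rank"] == 1).mean())
    top2 = float((df["causal_rank"] <= 2).mean())
    return rank1, top2, df


def build_report(patient_id: str, calls: Sequence[TriageCall]) -> TriageReport:
    """Summarize a patient's prioritized calls: the top pathogenic locus (or
    the carrier state, or no known repeat expansion).  Multiple pathogenic
    hits are all retained and flagged."""
    pathogenic = [c for c in calls if c.verdict == "pathogenic"]
    carriers = [c for c in calls if c.verdict == "carrier"]
    if pathogenic:
        summary = f"pathogenic: {pathogenic[0].locus_id}"
        if len(pathogenic) > 1:
            summary += " (multiple)"
    elif carriers:
        summary = f"carrier: {carriers[0].locus_id}"
    else:
        summary = NO_EXPANSION
    return TriageReport(patient_id, tuple(calls), summary,
                        multiple_hits=len(pathogenic) > 1)


def genotype_snp(sam_path, snp: SnpTarget, min_support: int = 2,
                 min_minor_fraction: float = 0.2) -> str:
    """Pileup genotype at a linked SNP: hom-ref / het / hom-alt by the
    >=20% minor-allele-fraction rule, or no-call below ``min_support``
    covering reads.  Informational only — it never changes a triage
    verdict (a negative linked SNP cannot exclude the diagnosis)."""
    counts = {"ref": 0, "alt": 0, "other": 0}
    pos0 = snp.pos - 1
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for aln in sam:
            if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
                    or aln.reference_name != snp.chrom):
                continue
            if not (aln.reference_start <= pos0 < aln.reference_end):
                continue
            base = None
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                if rpos == pos0:
                    base = aln.query_sequence[qpos]
                    break
            if base is None:
                continue
            if base == snp.ref_allele:
                counts["ref"] += 1
            elif base == snp.alt_allele:
                counts["alt"] += 1
            else:
                counts["other"] += 1
    total = counts["ref"] + counts["alt"]
    if total < min_support:
        return "no-call"
    alt_frac = counts["alt"] / total
    if alt_frac >= 1 - min_minor_fraction:
        return "hom-alt"
    if alt_frac >= min_minor_fraction:
        return "het"
    return "hom-ref"
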