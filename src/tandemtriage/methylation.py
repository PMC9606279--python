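"""Allele-level CpG methylation of expanded repeats.

Input is a plain per-read probability table (read_id, contig, pos, prob)
holding the basecaller's 5mC probabilities; reads are partitioned into
alleles with the genotyper's supporting-read sets.  An allele is called
hypermethylated / unmethylated / partial from the fraction of (read, CpG)
observations with probability >= 0.5, mirroring the extremes seen in
practice (an asymptomatic carrier's extremely long, hypermethylated
expansion vs unmethylated symptomatic expansions).

``bisulfite_like_convert`` performs the in-silico bisulfite-style
transform — unmethylated cytosines become thymines — so methylation can be
inspected with ordinary sequence tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genotyper import LocusGenotype

__all__ = [
    "MethylationCall",
    "bisulfite_like_convert",
    "allele_methylation",
]

HYPER_THRESHOLD = 0.6
UNMETH_THRESHOLD = 0.2
MIN_CPG = 10


@dataclass(frozen=True)
class MethylationCall:
    locus_id: str
    allele_index: int
    mean_meth_fraction: float | None
    n_cpg: int
    n_reads: int
    label: str   # hypermethylated | unmethylated | partial | no-call


def bisulfite_like_convert(sequence: str,
                           probs: Mapping[int, float] | Sequence[float],
                           threshold: float = 0.5) -> str:
    """Convert unmethylated cytosines to thymines.

    ``probs`` is either a dense per-base 5mC probability track (same length
    as the sequence) or a sparse {position: prob} mapping; cytosines with
    no recorded probability are treated as unmethylated.  Idempotent and
    length-preserving.
    """
    if not isinstance(probs, Mapping):
        if len(probs) != len(sequence):
            raise ValueError(
                f"probability track length {len(probs)} != sequence length "
                f"{len(sequence)}")
        probs = {i: p for i, p in enumerate(probs)}
    out = []
    for i, base in enumerate(sequence):
        if base == "C" and probs.get(i, 0.0) < threshold:
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


def allele_methylation(meth_table: pd.DataFrame,
                       genotype: LocusGenotype,
                       min_cpg: int = MIN_CPG,
                       hyper_threshold: float = HYPER_THRESHOLD,
                       unmeth_threshold: float = UNMETH_THRESHOLD,
                       ) -> list[MethylationCall]:
    """Classify each allele's methylation from per-read CpG probabilities.

    Observations are pooled over each allele's supporting reads; fewer
    than ``min_cpg`` (read, CpG) observations — or an allele with no reads
    — yields no-call.
    """
    required = {"read_id", "prob"}
    if not required <= set(meth_table.columns):
        raise ValueError(f"methylation table needs columns {sorted(required)}")
    calls = []
    for allele_index, reads in enumerate(genotype.supporting_reads):
        if genotype.homozygous and allele_index == 1:
            # both alleles share the read set; still report both entries
            pass
        if not reads:
            calls.append(MethylationCall(genotype.locus_id, allele_index,
                                         None, 0, 0, "no-call"))
            continue
        sub = meth_table[meth_table["read_id"].isin(reads)]
        n_cpg = len(sub)
        n_reads = sub["read_id"].nunique()
        if n_cpg < min_cpg:
            calls.append(MethylationCall(genotype.locus_id, allele_index,
                                         None, n_cpg, n_reads, "no-call"))
            continue
        frac = float((sub["prob"] >= 0.5).mean())
        if frac >= hyper_threshold:
            label = "hypermethylated"
        elif frac <= unmeth_threshold:
            label = "unmethylated"
        else:
            label = "partial"
        calls.append(MethylationCall(genotype.locus_id, allele_index,
                                     frac, n_cpg, n_reads, label))
    return calls
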