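"""Rank catalog loci for one patient against a control cohort.

The diagnostic flow does not call pathogenicity here — it orders loci by
how far the patient's repeat length change exceeds anything seen in the
controls, so an examiner (or the evaluator module) can walk the list from
rank 1.  The score is bp-scaled, ``(patient_stat - control_max) x
motif_len``, so a pentanucleotide expansion of hundreds of units outranks a
trinucleotide gain of a few units; the patient statistic is the m-th
largest per-read copy change (m = max(2, ceil(0.1 n))), robust to a single
chimeric or mis-mapped read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .catalog import Catalog
from .genotyper import ReadRepeatMeasurement

__all__ = [
    "ControlTable",
    "RankedLocus",
    "build_control_table",
    "rank_loci",
    "ranked_to_frame",
]

log = logging.getLogger(__name__)

#: sentinel score for loci with insufficient spanning support
NO_SUPPORT_SCORE = -math.inf


@dataclass(frozen=True)
class ControlTable:
    """Per-locus control allele copy changes (two alleles per control)."""

    copy_changes: dict[str, tuple[int, ...]]

    def __post_init__(self):
        for locus_id, values in self.copy_changes.items():
            if len(values) < 2:
                raise ValueError(
                    f"{locus_id}: need >=2 control alleles, got {len(values)}")

    def control_max(self, locus_id: str) -> int:
        return max(self.copy_changes[locus_id])

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.copy_changes


@dataclass(frozen=True)
class RankedLocus:
    locus_id: str
    gene: str
    patient_stat: int | None
    control_max: int
    score: float
    rank: int
    n_spanning: int
    flagged: bool = False      # True when support was insufficient


def build_control_table(controls: pd.DataFrame,
                        catalog: Catalog) -> ControlTable:
    """Build a control table from a cohort frame with columns
    ``locus_id, sample_id, allele_index`` and either ``copy_change`` or
    ``allele_units`` (converted via the catalog's reference unit counts)."""
    if controls.empty:
        raise ValueError("empty control table")
    df = controls.copy()
    if "copy_change" not in df.columns:
        if "allele_units" not in df.columns:
            raise ValueError("controls need copy_change or allele_units")
        ref = {l.locus_id: l.ref_units for l in catalog.loci}
        df["copy_change"] = df.apply(
            lambda r: int(r["allele_units"]) - ref[r["locus_id"]], axis=1)
    missing = [l.locus_id for l in catalog.loci
               if l.locus_id not in set(df["locus_id"])]
    if missing:
        raise ValueError(f"controls missing loci: {', '.join(missing)}")
    n_controls = df["sample_id"].nunique()
    if n_controls < 2:
        log.warning("control table has only %d control(s)", n_controls)
    table = {locus_id: tuple(int(v) for v in grp["copy_change"])
             for locus_id, grp in df.groupby("locus_id", sort=True)}
    return ControlTable(table)


def _patient_stat(copy_changes: Sequence[int]) -> int:
    """m-th largest per-read copy change, m = max(2, ceil(0.1 n))."""
    m = max(2, math.ceil(0.1 * len(copy_changes)))
    m = min(m, len(copy_changes))
    return sorted(copy_changes, reverse=True)[m - 1]


def rank_loci(measurements: Iterable[ReadRepeatMeasurement],
              controls: ControlTable,
              catalog: Catalog,
              min_support: int = 3) -> list[RankedLocus]:
    """Order loci by excess repeat change over the control cohort.

    Loci with fewer than ``min_support`` spanning reads are flagged and
    ranked last (sentinel score); ties are broken by genomic position.
    Ranks are a 1..n permutation and scores are non-increasing with rank.
    """
    by_locus: dict[str, list[int]] = {}
    for m in measurements:
        if m.spans_tract:
            by_locus.setdefault(m.locus_id, []).append(m.copy_change)
    entries = []
    for locus in catalog.loci:
        if locus.locus_id not in controls:
            raise ValueError(f"locus {locus.locus_id} absent from controls")
        changes = by_locus.get(locus.locus_id, [])
        cmax = controls.control_max(locus.locus_id)
        if len(changes) < min_support:
            entries.append((NO_SUPPORT_SCORE, locus, None, cmax,
                            len(changes), True))
        else:
            stat = _patient_stat(changes)
            score = (stat - cmax) * locus.motif_len
            entries.append((score, locus, stat, cmax, len(changes), False))
    entries.sort(key=lambda e: (-e[0], e[1].chrom, e[1].start))
    return [RankedLocus(locus_id=locus.locus_id, gene=locus.gene,
                        patient_stat=stat, control_max=cmax, score=score,
                        rank=i + 1, n_spanning=n, flagged=flagged)
            for i, (score, locus, stat, cmax, n, flagged)
            in enumerate(entries)]


def ranked_to_frame(ranked: Sequence[RankedLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.rank, r.locus_id, r.gene, r.patient_stat, r.control_max,
          r.score, r.n_spanning, r.flagged) for r in ranked],
        columns=["rank", "locus_id", "gene", "patient_stat", "control_max",
                 "score", "n_spanning", "flagged"])
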