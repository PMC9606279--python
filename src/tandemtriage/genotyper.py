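"""Per-read repeat copy-number measurement and two-allele genotyping.

The core measurement walks a read's CIGAR over the catalogued repeat tract:
insertions anchored within one motif length of the tract are counted as
gained repeat bases, deletions are counted by their overlap with the tract,
and the net bp change is converted to repeat units (rounded half toward
zero, so 1-2 bp of alignment jitter keeps unexpanded reads at zero).  Only
tract-spanning reads — anchored flank on both sides — enter genotyping.

Genotyping is a deterministic exhaustive two-cluster split of the sorted
per-read copy changes (exact for 1-D), collapsing to homozygous when the
cluster centers are closer than ``max(2, 10%)`` units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .catalog import Catalog, RepeatLocus

__all__ = [
    "ReadRepeatMeasurement",
    "LocusGenotype",
    "measure_read_copy_change",
    "measure_alignments",
    "genotype_locus",
    "genotype_all",
    "units_from_length",
    "histogram_table",
    "measurements_to_frame",
    "round_half_toward_zero",
]

log = logging.getLogger(__name__)

_MATCH_OPS = (0, 7, 8)   # M, =, X


def round_half_toward_zero(x: float) -> int:
    return int(math.copysign(math.ceil(abs(x) - 0.5), x))


@dataclass(frozen=True)
class ReadRepeatMeasurement:
    """One read's repeat length change at one locus."""

    read_id: str
    locus_id: str
    copy_change: int
    net_bp_change: int
    strand: str
    spans_tract: bool
    tract_sequence: str
    map_qual: int


@dataclass(frozen=True)
class LocusGenotype:
    """Two-allele unit-count estimate with its supporting-read partition.

    ``allele_units`` / ``allele_copy_change`` are ascending pairs (equal for
    homozygous calls) or ``None`` when undetermined.
    """

    locus_id: str
    allele_units: tuple[int, int] | None
    allele_copy_change: tuple[int, int] | None
    homozygous: bool
    supporting_reads: tuple[frozenset, frozenset]
    n_spanning: int

    @property
    def undetermined(self) -> bool:
        return self.allele_units is None


def units_from_length(tract_length_bp: int, motif_len: int) -> int:
    """Total expanded repeat length divided by the unit length (floor) —
    how unit counts are derived when contaminating sequence precludes
    direct unit counting."""
    if motif_len < 1:
        raise ValueError("motif_len must be >= 1")
    if tract_length_bp < 0:
        raise ValueError("tract_length_bp must be >= 0")
    return tract_length_bp // motif_len


def measure_read_copy_change(aln: pysam.AlignedSegment, locus: RepeatLocus,
                             anchor_bp: int = 100,
                             min_mapq: int = 1) -> ReadRepeatMeasurement | None:
    """Measure one alignment's repeat copy-number change at ``locus``.

    Returns ``None`` (with a log entry) for unmapped / secondary /
    supplementary records or map quality below ``min_mapq``.  Raises if the
    record is on a different contig than the locus.
    """
    if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
        log.debug("skipping non-primary record %s", aln.query_name)
        return None
    if aln.reference_name != locus.chrom:
        raise ValueError(
            f"alignment {aln.query_name} on {aln.reference_name}, locus "
            f"{locus.locus_id} on {locus.chrom}")
    if aln.mapping_quality < min_mapq:
        log.debug("skipping %s: mapq %d < %d", aln.query_name,
                  aln.mapping_quality, min_mapq)
        return None

    start, end = locus.start, locus.end
    w_lo, w_hi = start - locus.motif_len, end + locus.motif_len
    rpos = aln.reference_start
    qpos = 0
    net = 0
    qs = qe = None
    for op, ln in aln.cigartuples:
        if op in _MATCH_OPS:
            if qs is None and rpos + ln > start:
                qs = qpos + max(0, start - rpos)
            if qe is None and rpos >= end:
                qe = qpos
            if qe is None and rpos + ln > end:
                qe = qpos + (end - rpos)
            rpos += ln
            qpos += ln
        elif op == 1:  # insertion, anchored at current reference position
            if w_lo <= rpos <= w_hi:
                net += ln
            qpos += ln
        elif op == 2 or op == 3:  # deletion / skip
            if qs is None and rpos + ln > start:
                qs = qpos
            if qe is None and rpos >= end:
                qe = qpos
            if qe is None and rpos + ln > end:
                qe = qpos
            net -= max(0, min(end, rpos + ln) - max(start, rpos))
            rpos += ln
        elif op == 4:  # soft clip
            qpos += ln
        # hard clip / pad consume nothing relevant
    if qe is None and rpos >= end:
        qe = qpos

    spans = (aln.reference_start <= start - anchor_bp
             and aln.reference_end >= end + anchor_bp)
    tract_seq = ""
    if qs is not None and qe is not None and aln.query_sequence:
        tract_seq = aln.query_sequence[qs:qe]
    return ReadRepeatMeasurement(
        read_id=aln.query_name,
        locus_id=locus.locus_id,
        copy_change=round_half_toward_zero(net / locus.motif_len),
        net_bp_change=net,
        strand="-" if aln.is_reverse else "+",
        spans_tract=spans,
        tract_sequence=tract_seq,
        map_qual=aln.mapping_quality,
    )


def measure_alignments(sam_path: str | Path, catalog: Catalog,
                       anchor_bp: int = 100, min_mapq: int = 1,
                       window_bp: int = 0) -> list[ReadRepeatMeasurement]:
    """Measure every primary alignment against every catalog locus on its
    contig whose tract (padded by ``window_bp``) the alignment overlaps."""
    by_chrom: dict[str, list[RepeatLocus]] = {}
    for locus in catalog.loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    out: list[ReadRepeatMeasurement] = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name not in by_chrom:
                continue
            for locus in by_chrom[aln.reference_name]:
                if (aln.reference_start < locus.end + window_bp
                        and aln.reference_end > locus.start - window_bp):
                    m = measure_read_copy_change(aln, locus, anchor_bp,
                                                 min_mapq)
                    if m is not None:
                        out.append(m)
    return out


def _wcss(values: Sequence[int]) -> float:
    if not values:
        return 0.0
    mean = sum(values) / len(values)
    return sum((v - mean) ** 2 for v in values)


def _median_int(values: Sequence[int]) -> int:
    vs = sorted(values)
    n = len(vs)
    if n % 2:
        return vs[n // 2]
    return round_half_toward_zero((vs[n // 2 - 1] + vs[n // 2]) / 2)


def genotype_locus(measurements: Iterable[ReadRepeatMeasurement],
                   locus: RepeatLocus,
                   min_support: int = 3) -> LocusGenotype:
    """Crude two-allele prediction from spanning per-read copy changes.

    Exhaustive 1-D two-cluster split over the sorted copy changes
    minimizing within-cluster sum of squares; cluster medians become the
    allele copy changes unless they are within ``max(2, 0.1 x larger)``
    units of each other, in which case the call is homozygous at the
    overall median.  Fewer than ``min_support`` spanning reads yields an
    undetermined genotype.
    """
    ms = [m for m in measurements if m.spans_tract]
    ids = {m.locus_id for m in ms}
    if ids and ids != {locus.locus_id}:
        raise ValueError(f"mixed locus_ids in measurements: {sorted(ids)}")
    n = len(ms)
    if n < min_support:
        return LocusGenotype(locus.locus_id, None, None, False,
                             (frozenset(), frozenset()), n)
    ms_sorted = sorted(ms, key=lambda m: (m.copy_change, m.read_id))
    values = [m.copy_change for m in ms_sorted]
    best_k, best_cost = 1, math.inf
    for k in range(1, n):
        cost = _wcss(values[:k]) + _wcss(values[k:])
        if cost < best_cost - 1e-12:
            best_cost, best_k = cost, k
    lo, hi = values[:best_k], values[best_k:]
    c1, c2 = _median_int(lo), _median_int(hi)
    threshold = max(2, 0.1 * max(abs(c1), abs(c2)))
    if abs(c2 - c1) < threshold:
        allele = _median_int(values)
        reads = frozenset(m.read_id for m in ms_sorted)
        return LocusGenotype(
            locus.locus_id,
            (locus.ref_units + allele, locus.ref_units + allele),
            (allele, allele), True, (reads, reads), n)
    reads_lo = frozenset(m.read_id for m in ms_sorted[:best_k])
    reads_hi = frozenset(m.read_id for m in ms_sorted[best_k:])
    return LocusGenotype(
        locus.locus_id,
        (locus.ref_units + c1, locus.ref_units + c2),
        (c1, c2), False, (reads_lo, reads_hi), n)


def genotype_all(measurements: Iterable[ReadRepeatMeasurement],
                 catalog: Catalog,
                 min_support: int = 3) -> dict[str, LocusGenotype]:
    """Genotype every catalog locus from a mixed measurement collection."""
    by_locus: dict[str, list[ReadRepeatMeasurement]] = {}
    for m in measurements:
        by_locus.setdefault(m.locus_id, []).append(m)
    return {locus.locus_id: genotype_locus(
                by_locus.get(locus.locus_id, []), locus, min_support)
            for locus in catalog.loci}


def histogram_table(measurements: Iterable[ReadRepeatMeasurement]
                    ) -> pd.DataFrame:
    """Per-strand copy-change counts — the data behind the forward/reverse
    colored histogram of per-read repeat length changes."""
    rows = [(m.copy_change, m.strand) for m in measurements if m.spans_tract]
    if not rows:
        return pd.DataFrame(columns=["copy_change", "strand", "count"])
    df = pd.DataFrame(rows, columns=["copy_change", "strand"])
    out = (df.value_counts(["copy_change", "strand"]).rename("count")
           .reset_index().sort_values(["copy_change", "strand"])
           .reset_index(drop=True))
    return out


def measurements_to_frame(measurements: Iterable[ReadRepeatMeasurement],
                          with_sequence: bool = True) -> pd.DataFrame:
    cols = ["read_id", "locus_id", "strand", "net_bp_change", "copy_change",
            "spans_tract", "map_qual"]
    rows = [[m.read_id, m.locus_id, m.strand, m.net_bp_change, m.copy_change,
             m.spans_tract, m.map_qual] + (
                 [m.tract_sequence] if with_sequence else [])
            for m in measurements]
    if with_sequence:
        cols = cols + ["tract_sequence"]
    return pd.DataFrame(rows, columns=cols)
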