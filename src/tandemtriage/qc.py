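"""Enrichment and coverage QC for targeted runs.

Depth is computed from primary alignment spans after removing reads at or
below the length cutoff (adaptive sampling ejects non-target molecules
early, so very short reads are "out of target" rejects).  On-target depth
is averaged per locus window; off-target coverage is tiled in 5-kb bins
over the remaining genome, and the on/off ratio summarizes enrichment
(roughly three orders of magnitude for a successful run).  Down-sampling
and the serial-sample carryover estimate support depth titration and
time-lag (two samples per flow cell) QC.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "CoverageStats",
    "coverage_stats",
    "downsample",
    "carryover_estimate",
    "DEFAULT_MIN_READ_LEN",
    "OFF_TARGET_BIN_BP",
]

DEFAULT_MIN_READ_LEN = 1000
OFF_TARGET_BIN_BP = 5000


@dataclass(frozen=True)
class CoverageStats:
    per_locus_depth: dict[str, float]
    on_target_avg: float
    off_target_bins: pd.DataFrame     # contig, start, end, depth
    off_target_avg: float
    enrichment_ratio: float           # inf when off_target_avg == 0
    n_reads_filtered: int

    def summary(self) -> dict:
        ratio = ("inf" if math.isinf(self.enrichment_ratio)
                 else round(self.enrichment_ratio, 2))
        return {
            "on_target_avg": round(self.on_target_avg, 4),
            "off_target_avg": round(self.off_target_avg, 6),
            "enrichment_ratio": ratio,
            "n_reads_filtered": self.n_reads_filtered,
            "per_locus_depth": {k: round(v, 3)
                                for k, v in self.per_locus_depth.items()},
        }


def _depth_array(spans: Iterable[tuple[int, int]], length: int) -> np.ndarray:
    """Per-base depth over [0, length) from alignment spans (difference
    array accumulation)."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for start, end in spans:
        s, e = max(0, start), min(length, end)
        if e > s:
            diff[s] += 1
            diff[e] -= 1
    return np.cumsum(diff[:-1])


def coverage_stats(sam_path: str | Path,
                   target_bed: Sequence[tuple],
                   min_read_len: int = DEFAULT_MIN_READ_LEN,
                   bin_bp: int = OFF_TARGET_BIN_BP,
                   include_zero_bins: bool = True) -> CoverageStats:
    """Compute per-locus and off-target depth from a SAM/BAM.

    Reads of ``min_read_len`` bp or shorter are excluded before any depth
    computation.  Off-target bins tile every contig present in the
    alignment header outside the (merged) target windows; zero-coverage
    bins count toward the off-target average by default, making it a
    genome-wide mean.
    """
    if not target_bed:
        raise ValueError("empty target BED")
    spans_by_contig: dict[str, list[tuple[int, int]]] = {}
    n_filtered = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        contig_sizes = dict(zip(sam.references, sam.lengths))
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.query_length <= min_read_len:
                n_filtered += 1
                continue
            spans_by_contig.setdefault(aln.reference_name, []).append(
                (aln.reference_start, aln.reference_end))

    depth: dict[str, np.ndarray] = {}
    for contig, size in contig_sizes.items():
        depth[contig] = _depth_array(spans_by_contig.get(contig, []), size)

    per_locus: dict[str, float] = {}
    target_mask: dict[str, np.ndarray] = {
        c: np.zeros(s, dtype=bool) for c, s in contig_sizes.items()}
    for rec in target_bed:
        contig, start, end = rec[0], int(rec[1]), int(rec[2])
        name = rec[3] if len(rec) > 3 else f"{contig}:{start}-{end}"
        if contig not in depth:
            continue
        end_c = min(end, contig_sizes[contig])
        start_c = max(0, start)
        window = depth[contig][start_c:end_c]
        per_locus[name] = float(window.mean()) if len(window) else 0.0
        target_mask[contig][start_c:end_c] = True

    on_avg = (sum(per_locus.values()) / len(per_locus)) if per_locus else 0.0

    bin_rows = []
    for contig, size in contig_sizes.items():
        mask = target_mask[contig]
        d = depth[contig]
        for b0 in range(0, size, bin_bp):
            b1 = min(b0 + bin_bp, size)
            off = ~mask[b0:b1]
            if not off.any():
                continue  # bin entirely on-target
            bin_depth = float(d[b0:b1][off].mean())
            bin_rows.append((contig, b0, b1, bin_depth))
    bins = pd.DataFrame(bin_rows, columns=["contig", "start", "end", "depth"])
    if include_zero_bins or bins.empty:
        off_avg = float(bins["depth"].mean()) if not bins.empty else 0.0
    else:
        nz = bins[bins["depth"] > 0]
        off_avg = float(nz["depth"].mean()) if not nz.empty else 0.0
    ratio = (on_avg / off_avg) if off_avg > 0 else math.inf
    return CoverageStats(per_locus, on_avg, bins, off_avg, ratio, n_filtered)


def downsample(items: Sequence, proportion: float, seed: int = 0) -> list:
    """Sample ``round(proportion * n)`` items without replacement,
    deterministically per seed — the virtual-depth titration primitive
    (e.g. proportion 0.5 halves the expected target depth)."""
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    items = list(items)
    if proportion == 1.0:
        return items
    k = int(round(proportion * len(items)))
    rng = random.Random(seed)
    idx = sorted(rng.sample(range(len(items)), k))
    return [items[i] for i in idx]


def carryover_estimate(previous_run_depth: float,
                       residual_fraction: float = 0.001) -> float:
    """Expected depth carried over into the next serial sample on the same
    flow cell: previous depth x residual library fraction (a 99.9%
    effective wash leaves 0.001)."""
    if previous_run_depth < 0 or residual_fraction < 0:
        raise ValueError("inputs must be >= 0")
    return previous_run_depth * residual_fraction
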