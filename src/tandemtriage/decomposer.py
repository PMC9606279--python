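"""Consensus building and repeat-motif decomposition.

``build_consensus`` condenses an allele's spanning-read tract sequences
into one sequence (medoid read + per-column majority polish — deterministic
and adequate for unit counting).  ``decompose_motifs`` labels every base of
a tract with a catalogued motif unit or OTHER via a minimal-cost dynamic
program, which feeds waterfall matrices, per-motif composition counts, and
interruption calls (e.g. the CAACAG unit closing an expanded CAG tract, or
a benign CTA block 5' of a pathogenic CTG expansion).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .catalog import RepeatLocus
from .simulate import reverse_complement

__all__ = [
    "ConsensusResult",
    "MotifUnit",
    "MotifDecomposition",
    "InterruptionCall",
    "build_consensus",
    "decompose_motifs",
    "waterfall_matrix",
    "write_waterfall_tsv",
    "detect_interruptions",
]

OTHER = "OTHER"


@dataclass(frozen=True)
class ConsensusResult:
    locus_id: str
    allele_index: int
    sequence: str
    n_reads_used: int
    medoid_read_id: str


@dataclass(frozen=True)
class MotifUnit:
    """One labeled unit: [start, end) offsets into the decomposed sequence."""

    label: str          # motif string or OTHER
    start: int
    end: int
    mismatches: int = 0


@dataclass(frozen=True)
class MotifDecomposition:
    sequence: str
    units: tuple[MotifUnit, ...]
    composition: dict[str, int]
    other_bp: int

    @property
    def total_units(self) -> int:
        """Number of labeled motif units (OTHER runs excluded)."""
        return sum(c for label, c in self.composition.items()
                   if label != OTHER)

    def units_of(self, motifs: str | Iterable[str]) -> int:
        if isinstance(motifs, str):
            motifs = (motifs,)
        return sum(self.composition.get(m, 0) for m in motifs)


@dataclass(frozen=True)
class InterruptionCall:
    """A run of non-pathogenic units relative to the pathogenic block."""

    motif: str
    n_units: int
    position: str            # "5prime" | "internal" | "3prime" | "na"
    pathogenic_units: int


# ---------------------------------------------------------------------------
# consensus

def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def build_consensus(sequences: Sequence[tuple[str, str]] | Sequence[str],
                    locus_id: str = "", allele_index: int = 0
                    ) -> ConsensusResult:
    """Medoid + majority-polish consensus over one allele's tract reads.

    The medoid (minimum summed edit distance to the rest, ties to the
    first) anchors the column space; every read is globally aligned to it
    and each medoid column takes the majority base (ties keep the medoid
    base; a majority gap drops the column).  Insertions relative to the
    medoid are ignored — adequate for unit counting, not indel-perfect
    assembly.
    """
    if not sequences:
        raise ValueError("no sequences to build consensus from")
    if isinstance(sequences[0], str):
        records = [(f"read{i}", s) for i, s in enumerate(sequences)]
    else:
        records = list(sequences)
    if any(not seq for _, seq in records):
        raise ValueError("empty sequence in consensus input")
    if len(records) == 1:
        rid, seq = records[0]
        return ConsensusResult(locus_id, allele_index, seq, 1, rid)

    dist_sums = []
    for i, (_, a) in enumerate(records):
        dist_sums.append(sum(_edit_distance(a, b)
                             for j, (_, b) in enumerate(records) if i != j))
    medoid_i = min(range(len(records)), key=lambda i: (dist_sums[i], i))
    medoid_id, medoid = records[medoid_i]

    # votes[column][base]; '-' records a deletion vote
    votes: list[dict[str, int]] = [dict() for _ in medoid]
    for _, seq in records:
        res = edlib.align(seq, medoid, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, seq, medoid)
        col = 0
        for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
            if tc == "-":
                continue  # insertion relative to medoid: ignored
            votes[col][qc] = votes[col].get(qc, 0) + 1
            col += 1
    out = []
    for col, vote in enumerate(votes):
        ref_base = medoid[col]
        best = max(vote.values())
        winners = [b for b, c in vote.items() if c == best]
        base = ref_base if ref_base in winners else sorted(winners)[0]
        if base != "-":
            out.append(base)
    return ConsensusResult(locus_id, allele_index, "".join(out),
                           len(records), medoid_id)


# ---------------------------------------------------------------------------
# motif decomposition (dynamic program)

def decompose_motifs(sequence: str, motifs: Sequence[str],
                     max_mismatch_per_unit: int = 1) -> MotifDecomposition:
    """Minimal-cost partition of ``sequence`` into motif units and OTHER.

    Cost: 0 per exact unit, 1 per mismatched base inside a unit (allowed
    only for motifs of length >= 4, up to ``max_mismatch_per_unit``), 1 per
    OTHER base.  Equal-cost ties prefer fewer OTHER runs, then
    earlier-listed motifs (catalogs list pathogenic motifs first, so e.g.
    TGGAA beats TAGAA where both fit).  Any sequence decomposes — the worst
    case is all OTHER.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    motifs = [m.upper() for m in motifs]
    seq = sequence.upper()
    n = len(seq)
    INF = float("inf")
    # dp[i]: (cost, other_runs, first_is_other, choice) for suffix seq[i:]
    dp: list[tuple] = [(0, 0, False, None)] * (n + 1)
    for i in range(n - 1, -1, -1):
        best = None
        best_choice = None
        for mi, motif in enumerate(motifs):
            L = len(motif)
            if i + L > n:
                continue
            mm = sum(1 for a, b in zip(seq[i:i + L], motif) if a != b)
            limit = max_mismatch_per_unit if L >= 4 else 0
            if mm > limit:
                continue
            nxt = dp[i + L]
            key = (mm + nxt[0], nxt[1])
            if best is None or key < best:
                best = key
                best_choice = ("unit", motif, L, mm, False)
        nxt = dp[i + 1]
        runs = nxt[1] if nxt[2] else nxt[1] + 1
        key = (1 + nxt[0], runs)
        if best is None or key < best:
            best = key
            best_choice = ("other", None, 1, 0, True)
        dp[i] = (best[0], best[1], best_choice[4], best_choice)

    units: list[MotifUnit] = []
    composition: dict[str, int] = {}
    other_bp = 0
    i = 0
    while i < n:
        kind, motif, L, mm, _ = dp[i][3]
        if kind == "unit":
            units.append(MotifUnit(motif, i, i + L, mm))
            composition[motif] = composition.get(motif, 0) + 1
            i += L
        else:
            j = i
            while j < n and dp[j][3][0] == "other":
                j += 1
            units.append(MotifUnit(OTHER, i, j, 0))
            composition[OTHER] = composition.get(OTHER, 0) + 1
            other_bp += j - i
            i = j
    return MotifDecomposition(seq, tuple(units), composition, other_bp)


# ---------------------------------------------------------------------------
# waterfall

def waterfall_matrix(tract_records: Sequence[tuple[str, str, str]],
                     motifs: Sequence[str],
                     max_mismatch_per_unit: int = 1
                     ) -> list[tuple[str, str, list[str]]]:
    """Per-read rows of motif unit labels (the waterfall plot's data).

    ``tract_records`` are ``(read_id, tract_sequence, strand)``;
    reverse-strand reads are reverse-complemented before decomposition so
    every row reads 5'->3' on the plus strand.  Rows are sorted by total
    labeled unit count, descending (longest expansion on top).
    """
    rows = []
    for read_id, seq, strand in tract_records:
        if not seq:
            continue
        oriented = reverse_complement(seq) if strand == "-" else seq
        dec = decompose_motifs(oriented, motifs, max_mismatch_per_unit)
        labels = []
        for u in dec.units:
            if u.label == OTHER:
                labels.extend([OTHER] * (u.end - u.start))
            else:
                labels.append(u.label)
        rows.append((read_id, strand, labels, dec.total_units))
    rows.sort(key=lambda r: (-r[3], r[0]))
    return [(rid, strand, labels) for rid, strand, labels, _ in rows]


def waterfall_from_measurements(measurements, motifs: Sequence[str],
                                max_mismatch_per_unit: int = 1
                                ) -> list[tuple[str, str, list[str]]]:
    """Waterfall rows from genotyper measurements, whose tract sequences
    are already in reference (plus) orientation — no re-orientation
    needed, but rows keep their sequencing strand so strand-specific
    artifacts (e.g. AAGG miscalls on one strand) remain visible."""
    records = [(m.read_id, m.tract_sequence, "+")
               for m in measurements if m.spans_tract and m.tract_sequence]
    strand_of = {m.read_id: m.strand for m in measurements}
    rows = waterfall_matrix(records, motifs, max_mismatch_per_unit)
    return [(rid, strand_of.get(rid, "+"), labels)
            for rid, _, labels in rows]


def write_waterfall_tsv(rows: Sequence[tuple[str, str, list[str]]],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstrand\tunits\n")
        for read_id, strand, labels in rows:
            fh.write(f"{read_id}\t{strand}\t{','.join(labels)}\n")


# ---------------------------------------------------------------------------
# interruptions

def detect_interruptions(decomposition: MotifDecomposition,
                         locus: RepeatLocus) -> list[InterruptionCall]:
    """Maximal runs of non-pathogenic motif units, placed 5'/internal/3'
    relative to the pathogenic-motif block (OTHER runs are not calls)."""
    units = decomposition.units
    path_set = set(locus.pathogenic_motifs)
    path_idx = [i for i, u in enumerate(units) if u.label in path_set]
    n_path = len(path_idx)
    first_p = path_idx[0] if path_idx else None
    last_p = path_idx[-1] if path_idx else None
    calls: list[InterruptionCall] = []
    i = 0
    while i < len(units):
        label = units[i].label
        if label in path_set or label == OTHER:
            i += 1
            continue
        j = i
        while j < len(units) and units[j].label == label:
            j += 1
        if first_p is None:
            position = "na"
        elif j <= first_p:
            position = "5prime"
        elif i > last_p:
            position = "3prime"
        else:
            position = "internal"
        calls.append(InterruptionCall(label, j - i, position, n_path))
        i = j
    return calls
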