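"""Synthetic targeted long-read data with exact ground truth.

The simulator emulates what a targeted nanopore run of a repeat-expansion
panel looks like to the downstream pipeline: a mini-genome with one contig
per catalogued locus (random flanks around the reference repeat tract),
diploid per-locus alleles given as ordered motif compositions, lognormal
read lengths, per-base substitution / indel errors, an optional
strand-specific motif-miscall artifact (the AAGGG->AAGG basecalling error
seen at RFC1-like loci), a polymorphic control cohort, and allele-level CpG
methylation probabilities.

Reads are emitted with their exact alignment (the CIGAR is derived from the
known edit script), so no external aligner is needed to exercise the
genotyper: the SAM records *are* the truth, perturbed only by the simulated
errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .catalog import Catalog, RepeatLocus, SnpTarget

__all__ = [
    "AlleleSpec",
    "MotifMiscall",
    "SimSpec",
    "MiniGenome",
    "SimRead",
    "SimResult",
    "build_mini_genome",
    "simulate_reads",
    "simulate_controls",
    "simulate_methylation",
    "reverse_complement",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlleleSpec:
    """One allele's repeat tract as an ordered motif composition,
    e.g. ``(("TTTCA", 167), ("TTTTA", 500))``."""

    units: tuple[tuple[str, int], ...]

    def __post_init__(self):
        for motif, count in self.units:
            if count < 0:
                raise ValueError("unit counts must be >= 0")
            if not motif:
                raise ValueError("empty motif")

    @property
    def sequence(self) -> str:
        return "".join(m * c for m, c in self.units)

    @property
    def total_bp(self) -> int:
        return sum(len(m) * c for m, c in self.units)

    @classmethod
    def simple(cls, motif: str, count: int) -> "AlleleSpec":
        return cls(((motif, count),))


@dataclass(frozen=True)
class MotifMiscall:
    """Strand-specific whole-unit miscall artifact: each ``source_motif``
    unit sequenced on ``strand`` is corrupted to ``corrupt_motif`` with
    probability ``prob`` (per unit)."""

    source_motif: str
    corrupt_motif: str
    prob: float
    strand: str = "-"

    def __post_init__(self):
        if not 0 <= self.prob <= 1:
            raise ValueError("prob must be in [0,1]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.corrupt_motif) > len(self.source_motif):
            raise ValueError("corrupt motif longer than source not supported")


@dataclass
class SimSpec:
    """Study conditions for one simulated sample.

    Defaults mirror a targeted nanopore run: ~20x spanning depth, reads
    lognormal around 20 kb (DNA sheared to tens of kb), ~2% total error
    split 1% substitution / 0.5% insertion / 0.5% deletion.
    """

    catalog: Catalog
    alleles: dict[str, tuple[AlleleSpec, AlleleSpec]]
    depth: float = 20.0
    read_len_mean: float = 20_000.0
    read_len_sigma: float = 0.5
    read_len_min: int = 2_000
    read_len_max: int = 100_000
    sub_rate: float = 0.01
    ins_rate: float = 0.005
    del_rate: float = 0.005
    motif_miscall: MotifMiscall | None = None
    flank_bp: int = 8_000
    offtarget_fraction: float = 0.25
    #: per SNP target: "hom-ref" | "het" | "hom-alt"
    snp_genotypes: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 1:
                raise ValueError("error rates must be in [0,1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        unknown = set(self.alleles) - set(self.catalog.locus_ids)
        if unknown:
            raise ValueError(f"alleles given for unknown loci: {unknown}")

    def allele_pair(self, locus: RepeatLocus) -> tuple[AlleleSpec, AlleleSpec]:
        """Allele pair for a locus; unspecified loci are homozygous
        reference (ref_units of the primary motif)."""
        if locus.locus_id in self.alleles:
            return self.alleles[locus.locus_id]
        ref = AlleleSpec.simple(locus.ref_motif, locus.ref_units)
        return (ref, ref)


@dataclass
class MiniGenome:
    """One contig per locus (named by locus_id) plus one short contig per
    SNP target; ``catalog`` is rebased onto these contigs."""

    contigs: dict[str, str]
    catalog: Catalog
    flank_bp: int

    @property
    def contig_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def build_mini_genome(catalog: Catalog, flank_bp: int = 8_000,
                      seed: int = 0) -> MiniGenome:
    """Synthesize a reference mini-genome: for each locus, seeded-random
    flank + ref_units x primary motif + seeded-random flank.  Deterministic
    for a fixed seed."""
    if flank_bp < 1000:
        raise ValueError("flank_bp must be >= 1000")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    new_loci = []
    for locus in catalog.loci:
        tract = locus.ref_motif * locus.ref_units
        contigs[locus.locus_id] = (_random_dna(rng, flank_bp) + tract
                                   + _random_dna(rng, flank_bp))
        new_loci.append(RepeatLocus(
            locus_id=locus.locus_id, gene=locus.gene, disease=locus.disease,
            chrom=locus.locus_id, start=flank_bp,
            end=flank_bp + len(tract) if tract else flank_bp + 1,
            pathogenic_motifs=locus.pathogenic_motifs,
            benign_motifs=locus.benign_motifs,
            interruption_motifs=locus.interruption_motifs,
            ref_units=locus.ref_units,
            normal_max_units=locus.normal_max_units,
            pathogenic_min_units=locus.pathogenic_min_units,
            inheritance=locus.inheritance, motif_len=locus.motif_len))
    new_snps = []
    for snp in catalog.snps:
        left = _random_dna(rng, flank_bp)
        right = _random_dna(rng, flank_bp)
        contigs[snp.snp_id] = left + snp.ref_allele + right
        new_snps.append(SnpTarget(
            snp_id=snp.snp_id, chrom=snp.snp_id, pos=flank_bp + 1,
            ref_allele=snp.ref_allele, alt_allele=snp.alt_allele,
            linked_disease=snp.linked_disease, window_bp=snp.window_bp))
    genome_size = sum(len(s) for s in contigs.values())
    rebased = Catalog(tuple(new_loci), tuple(new_snps), genome_size)
    return MiniGenome(contigs, rebased, flank_bp)


@dataclass
class SimRead:
    """A simulated read in reference orientation with its exact alignment."""

    read_id: str
    locus_id: str
    contig: str
    allele_index: int
    strand: str
    seq: str                 # reference-orientation sequence (SAM SEQ)
    pos: int                 # 0-based leftmost aligned reference position
    cigar: str
    spans_tract: bool
    true_copy_change: int

    @property
    def fastq_seq(self) -> str:
        """As sequenced: reverse-complemented for minus-strand reads."""
        return self.seq if self.strand == "+" else reverse_complement(self.seq)


@dataclass
class SimResult:
    reads: list[SimRead]
    genome: MiniGenome
    spec: SimSpec
    warnings: list[str] = field(default_factory=list)

    def truth_table(self) -> pd.DataFrame:
        rows = [(r.read_id, r.locus_id, r.allele_index, r.true_copy_change,
                 r.strand, r.spans_tract) for r in self.reads]
        return pd.DataFrame(rows, columns=[
            "read_id", "locus_id", "allele_index", "true_copy_change",
            "strand", "spans_tract"])

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for w in self.warnings:
                fh.write(f"# WARNING: {w}\n")
            self.truth_table().to_csv(fh, sep="\t", index=False)

    def write_fastq(self, path: str | Path, qual_char: str = "5") -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                seq = r.fastq_seq
                fh.write(f"@{r.read_id}\n{seq}\n+\n{qual_char * len(seq)}\n")

    def sam_header(self) -> dict:
        return {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": size}
                   for name, size in self.genome.contig_sizes.items()],
        }

    def to_alignments(self) -> Iterable[pysam.AlignedSegment]:
        """Yield in-memory alignment records (same content as write_sam)."""
        header = pysam.AlignmentHeader.from_dict(self.sam_header())
        for r in self.reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = header.get_tid(r.contig)
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigarstring = r.cigar
            yield a

    def write_sam(self, path: str | Path) -> None:
        header = self.sam_header()
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            for r in self.reads:
                a = pysam.AlignedSegment(sam.header)
                a.query_name = r.read_id
                a.query_sequence = r.seq
                a.flag = 16 if r.strand == "-" else 0
                a.reference_id = sam.header.get_tid(r.contig)
                a.reference_start = r.pos
                a.mapping_quality = 60
                a.cigarstring = r.cigar
                a.query_qualities = pysam.qualitystring_to_array(
                    "5" * len(r.seq))
                sam.write(a)


# ---------------------------------------------------------------------------
# read construction

def round_half_toward_zero(x: float) -> int:
    """Round to nearest integer, ties toward zero (shared with genotyper)."""
    return int(math.copysign(math.ceil(abs(x) - 0.5), x))


def _true_copy_change(allele_bp: int, ref_bp: int, motif_len: int) -> int:
    return round_half_toward_zero((allele_bp - ref_bp) / motif_len)


def _build_pairs(hap_seq: str, hs: int, he: int, s: int,
                 alen: int, rlen: int) -> tuple[list[int], list[str | None]]:
    """Aligned pairs (ref position or -1, base or None) for the haplotype
    window [hs, he).  The haplotype is left-flank + allele tract + right
    flank; the reference shares the flanks around a tract of ``rlen`` bp
    starting at reference position ``s`` (== haplotype tract start)."""
    refp: list[int] = []
    bases: list[str | None] = []
    m = min(alen, rlen)
    # left flank (identical coordinates)
    a, b = hs, min(he, s)
    if b > a:
        refp.extend(range(a, b))
        bases.extend(hap_seq[a:b])
    # matched part of the tract
    a, b = max(hs, s), min(he, s + m)
    if b > a:
        refp.extend(range(a, b))
        bases.extend(hap_seq[a:b])
    if alen > rlen:
        # inserted tract bases (anchored at the tract 3' end)
        a, b = max(hs, s + rlen), min(he, s + alen)
        if b > a:
            refp.extend([-1] * (b - a))
            bases.extend(hap_seq[a:b])
    elif rlen > alen and hs < s + alen and he > s + alen:
        # reference bases deleted from this haplotype
        refp.extend(range(s + alen, s + rlen))
        bases.extend([None] * (rlen - alen))
    # right flank (shifted by rlen - alen)
    shift = rlen - alen
    a, b = max(hs, s + alen), he
    if b > a:
        refp.extend(range(a + shift, b + shift))
        bases.extend(hap_seq[a:b])
    return refp, bases


def _apply_miscall(refp: list[int], bases: list[str | None], hs: int,
                   allele: AlleleSpec, tract_start: int,
                   miscall: MotifMiscall, rng: np.random.Generator) -> None:
    """Corrupt whole source-motif units (in place) for a read window that
    starts at haplotype position ``hs``.  Only units fully inside the read
    are touched."""
    src, dst = miscall.source_motif, miscall.corrupt_motif
    off = tract_start
    for motif, count in allele.units:
        L = len(motif)
        if motif == src and count:
            hits = np.flatnonzero(rng.random(count) < miscall.prob)
            for k in hits:
                u0 = off + int(k) * L
                i0, i1 = u0 - hs, u0 - hs + L
                if i0 < 0 or i1 > len(bases):
                    continue  # unit not fully inside the read
                for j in range(L):
                    if j < len(dst):
                        bases[i0 + j] = dst[j]
                    else:
                        # dropped base: deletion vs reference, or removed
                        # insertion
                        bases[i0 + j] = None if refp[i0 + j] >= 0 else ""
        off += L * count
    # purge zero-length sentinels (removed inserted bases)
    if any(b == "" for b in bases):
        keep = [i for i, b in enumerate(bases) if b != ""]
        refp[:] = [refp[i] for i in keep]
        bases[:] = [bases[i] for i in keep]


def _apply_errors(refp: list[int], bases: list[str | None],
                  spec: SimSpec, rng: np.random.Generator
                  ) -> tuple[list[int], list[str | None]]:
    n = len(refp)
    if n == 0 or (spec.sub_rate == 0 and spec.ins_rate == 0
                  and spec.del_rate == 0):
        return refp, bases
    r = rng.random((3, n))
    subs = r[0] < spec.sub_rate
    dels = r[1] < spec.del_rate
    inss = r[2] < spec.ins_rate
    sub_bases = rng.integers(0, 3, size=int(subs.sum()))
    ins_bases = rng.integers(0, 4, size=int(inss.sum()))
    alphabet = "ACGT"
    out_r: list[int] = []
    out_b: list[str | None] = []
    si = ii = 0
    for i in range(n):
        base = bases[i]
        if base is not None:           # real read base
            if dels[i]:
                if refp[i] >= 0:
                    out_r.append(refp[i])
                    out_b.append(None)  # M -> D
                # deleted inserted base vanishes entirely
            else:
                if subs[i]:
                    # substitute with one of the three other bases
                    cur = alphabet.find(base)
                    pick = int(sub_bases[si])
                    if cur >= 0 and pick >= cur:
                        pick += 1
                    base = alphabet[pick % 4]
                    si += 1
                out_r.append(refp[i])
                out_b.append(base)
            if inss[i]:
                out_r.append(-1)
                out_b.append(alphabet[int(ins_bases[ii])])
                ii += 1
        else:                          # pre-existing deletion column
            out_r.append(refp[i])
            out_b.append(None)
    return out_r, out_b


def _pairs_to_alignment(refp: list[int], bases: list[str | None]
                        ) -> tuple[str, int, str]:
    """Compress aligned pairs to (SEQ, POS, CIGAR), trimming edge deletions."""
    # trim leading/trailing deletion columns
    lo, hi = 0, len(refp)
    while lo < hi and bases[lo] is None:
        lo += 1
    while hi > lo and bases[hi - 1] is None:
        hi -= 1
    pos = -1
    ops: list[tuple[str, int]] = []
    seq_parts: list[str] = []
    for i in range(lo, hi):
        if bases[i] is None:
            op = "D"
        elif refp[i] >= 0:
            op = "M"
        else:
            op = "I"
        if op != "D":
            seq_parts.append(bases[i])
        if op == "M" and pos < 0:
            pos = refp[i]
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    # an alignment cannot start/end with I either; fold edge insertions
    # into soft clips
    cigar_parts = []
    for idx, (op, ln) in enumerate(ops):
        if op == "I" and (idx == 0 or idx == len(ops) - 1):
            op = "S"
        cigar_parts.append(f"{ln}{op}")
    return "".join(seq_parts), pos, "".join(cigar_parts)


def _draw_read_len(rng: np.random.Generator, spec: SimSpec) -> int:
    mu = math.log(spec.read_len_mean) - spec.read_len_sigma ** 2 / 2
    L = int(rng.lognormal(mu, spec.read_len_sigma))
    return max(spec.read_len_min, min(spec.read_len_max, L))


def simulate_reads(spec: SimSpec, genome: MiniGenome | None = None
                   ) -> SimResult:
    """Simulate a diploid targeted run over the catalog.

    Per locus, each allele contributes ``round(depth/2)`` tract-spanning
    reads (start uniform over valid positions) plus a fraction of
    flank-only reads; every read gets a uniform strand, lognormal length,
    per-base errors, and (optionally) the strand-specific motif miscall.
    The returned SAM truth reflects the exact edit script of each read.
    """
    rng = np.random.default_rng(spec.seed)
    if genome is None:
        genome = build_mini_genome(spec.catalog, spec.flank_bp, spec.seed)
    reads: list[SimRead] = []
    warnings: list[str] = []
    anchor_margin = 400          # guaranteed flank beyond the tract
    n_span_allele = int(spec.depth / 2 + 0.5)
    for orig_locus in spec.catalog.loci:
        locus = genome.catalog.get(orig_locus.locus_id)
        contig = genome.contigs[locus.locus_id]
        clen = len(contig)
        s = genome.flank_bp
        rlen = locus.tract_len if locus.ref_units else 0
        pair = spec.allele_pair(orig_locus)
        if n_span_allele == 0:
            warnings.append(f"{locus.locus_id}: requested depth {spec.depth}"
                            " yields zero spanning reads")
        for ai, allele in enumerate(pair):
            aseq = allele.sequence
            alen = len(aseq)
            hap = contig[:s] + aseq + contig[s + rlen:]
            hlen = len(hap)
            tcc = _true_copy_change(alen, rlen, locus.motif_len)
            n_extra = int(math.ceil(n_span_allele * spec.offtarget_fraction))
            for k in range(n_span_allele):
                L = _draw_read_len(rng, spec)
                need = alen + 2 * anchor_margin
                L = min(max(L, need), hlen)
                lo = max(0, s + alen + anchor_margin - L)
                hi = min(s - anchor_margin, hlen - L)
                if hi < lo:      # tract + margins exceed contig; span all
                    hs = 0
                    L = hlen
                else:
                    hs = int(rng.integers(lo, hi + 1))
                read = _make_read(spec, rng, hap, hs, hs + L, s, alen, rlen,
                                  locus, allele,
                                  f"{locus.locus_id}_a{ai}_{k:04d}",
                                  ai, tcc, spans=True)
                if read:
                    reads.append(read)
            # flank-only reads exercise spanning logic and off-tract depth
            for k in range(n_extra):
                side = int(rng.integers(0, 2))
                L = min(_draw_read_len(rng, spec),
                        max(1000, genome.flank_bp - 200))
                if side == 0:
                    hs = int(rng.integers(0, max(1, s - anchor_margin - L)))
                else:
                    lo2 = s + alen + anchor_margin
                    hs = int(rng.integers(lo2, max(lo2 + 1, hlen - L)))
                    hs = min(hs, hlen - L)
                read = _make_read(spec, rng, hap, hs, hs + L, s, alen, rlen,
                                  locus, allele,
                                  f"{locus.locus_id}_a{ai}_f{k:04d}",
                                  ai, tcc, spans=False)
                if read:
                    reads.append(read)
    # SNP-target contigs: plain reads spanning the SNP position, alleles
    # per the requested genotype (default hom-ref)
    for snp in genome.catalog.snps:
        contig = genome.contigs[snp.chrom]
        pos0 = snp.pos - 1
        gt = spec.snp_genotypes.get(snp.snp_id, "hom-ref")
        if gt not in ("hom-ref", "het", "hom-alt"):
            raise ValueError(f"unknown SNP genotype {gt!r}")
        n_reads = int(spec.depth + 0.5)
        for k in range(n_reads):
            carries_alt = (gt == "hom-alt"
                           or (gt == "het" and k % 2 == 1))
            hap = contig if not carries_alt else (
                contig[:pos0] + snp.alt_allele + contig[pos0 + 1:])
            L = min(_draw_read_len(rng, spec), len(hap))
            lo = max(0, pos0 + 200 - L)
            hi = min(pos0 - 200, len(hap) - L)
            hs = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
            refp = list(range(hs, hs + L))
            bases: list[str | None] = list(hap[hs:hs + L])
            refp, bases = _apply_errors(refp, bases, spec, rng)
            seq, pos, cigar = _pairs_to_alignment(refp, bases)
            if not seq:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(SimRead(
                read_id=f"{snp.snp_id}_{k:04d}", locus_id=snp.snp_id,
                contig=snp.chrom, allele_index=int(carries_alt),
                strand=strand, seq=seq, pos=pos, cigar=cigar,
                spans_tract=False, true_copy_change=0))
    return SimResult(reads, genome, spec, warnings)


def _make_read(spec: SimSpec, rng: np.random.Generator, hap: str,
               hs: int, he: int, s: int, alen: int, rlen: int,
               locus: RepeatLocus, allele: AlleleSpec, read_id: str,
               allele_index: int, tcc: int, spans: bool) -> SimRead | None:
    strand = "+" if rng.random() < 0.5 else "-"
    refp, bases = _build_pairs(hap, hs, he, s, alen, rlen)
    if (spec.motif_miscall is not None
            and strand == spec.motif_miscall.strand):
        _apply_miscall(refp, bases, hs, allele, s, spec.motif_miscall, rng)
    refp, bases = _apply_errors(refp, bases, spec, rng)
    seq, pos, cigar = _pairs_to_alignment(refp, bases)
    if not seq or pos < 0:
        return None
    return SimRead(read_id=read_id, locus_id=locus.locus_id,
                   contig=locus.chrom, allele_index=allele_index,
                   strand=strand, seq=seq, pos=pos, cigar=cigar,
                   spans_tract=spans, true_copy_change=tcc)


# ---------------------------------------------------------------------------
# control cohort and methylation

def simulate_controls(catalog: Catalog, n: int = 27, jitter_units: int = 3,
                      seed: int = 0) -> pd.DataFrame:
    """Simulate a control cohort: per control and locus, two allele unit
    counts drawn uniformly from ``ref_units +/- jitter_units`` (floored at
    0).  27 controls give the 54 control alleles per locus the
    prioritization step compares against."""
    if n < 1:
        raise ValueError("need at least one control")
    if jitter_units < 0:
        raise ValueError("jitter_units must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for locus in catalog.loci:
        draws = rng.integers(-jitter_units, jitter_units + 1,
                             size=(n, 2)) if jitter_units else \
            np.zeros((n, 2), dtype=int)
        for ci in range(n):
            for ai in range(2):
                units = max(0, locus.ref_units + int(draws[ci, ai]))
                rows.append((locus.locus_id, f"control{ci:02d}", ai, units,
                             units - locus.ref_units))
    return pd.DataFrame(rows, columns=[
        "locus_id", "sample_id", "allele_index", "allele_units",
        "copy_change"])


def simulate_methylation(result: SimResult,
                         meth_profile: dict[str, tuple[float, float]],
                         seed: int = 0,
                         concentration: float = 10.0) -> pd.DataFrame:
    """Per-read CpG 5mC probabilities around each allele's profile.

    For every CpG dinucleotide on every read of a profiled locus, a
    probability is drawn from a beta distribution with mean equal to the
    allele's methylation level (extreme profiles <=0.01 / >=0.99 draw from
    narrow uniform bands so that fully (un)methylated alleles stay clean).
    Positions are reported as read-anchored reference offsets.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for read in result.reads:
        if read.locus_id not in meth_profile:
            continue
        p = meth_profile[read.locus_id][read.allele_index]
        if not 0 <= p <= 1:
            raise ValueError("methylation profile must be in [0,1]")
        seq = read.seq
        sites = [i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"]
        if not sites:
            continue
        if p <= 0.01:
            probs = rng.uniform(0.0, 0.1, size=len(sites))
        elif p >= 0.99:
            probs = rng.uniform(0.9, 1.0, size=len(sites))
        else:
            probs = rng.beta(p * concentration, (1 - p) * concentration,
                             size=len(sites))
        for i, pr in zip(sites, probs):
            rows.append((read.read_id, read.contig, read.pos + i,
                         round(float(pr), 4)))
    return pd.DataFrame(rows, columns=["read_id", "contig", "pos", "prob"])
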