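"""Disease-locus catalog: validation, serialization, and target-region design.

A catalog describes the tandem-repeat loci a targeted long-read run enriches
for (plus any linked SNPs, e.g. the SCA31-associated *PLEKHG4* variant).  Each
locus carries the reference repeat tract coordinates, the pathogenic / benign /
interrupting motif sets, the reference unit count, and optional clinical
unit-count thresholds.  The catalog is the single source of truth consumed by
the simulator, genotyper, prioritizer and evaluator.

Coordinates are 0-based half-open throughout (BED convention); SAM input is
converted on read by pysam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RepeatLocus",
    "SnpTarget",
    "Catalog",
    "CatalogError",
    "load_catalog",
    "load_default_catalog",
    "save_catalog",
    "make_target_bed",
    "merge_intervals",
    "target_fraction",
    "GRCH38_PRIMARY_BP",
]

#: GRCh38 primary-assembly length used to express target fractions.
GRCH38_PRIMARY_BP = 3_088_269_832

_CATALOG_COLUMNS = [
    "locus_id", "gene", "disease", "chrom", "start", "end",
    "pathogenic_motifs", "benign_motifs", "interruption_motifs",
    "ref_units", "normal_max_units", "pathogenic_min_units",
    "inheritance", "motif_len",
]

_SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele",
                "linked_disease", "window_bp"]

_INHERITANCE = {"AD", "AR", "XL", "unknown"}
_BASES = set("ACGT")


class CatalogError(ValueError):
    """Raised for malformed or internally inconsistent catalogs."""


@dataclass(frozen=True)
class RepeatLocus:
    """One catalogued disease locus.

    ``start``/``end`` delimit the reference repeat tract (0-based half-open).
    ``pathogenic_motifs`` are plus-strand unit strings ordered by priority
    (first = the primary disease motif); ``benign_motifs`` are polymorphic
    units at the same locus; ``interruption_motifs`` are non-canonical units
    that can interrupt or flank the disease repeat.  Unit-count thresholds
    (``normal_max_units``, ``pathogenic_min_units``) are ``None`` where no
    accepted clinical threshold is shipped; the evaluator then refuses to
    call the locus rather than guessing.
    """

    locus_id: str
    gene: str
    disease: str
    chrom: str
    start: int
    end: int
    pathogenic_motifs: tuple[str, ...]
    benign_motifs: tuple[str, ...] = ()
    interruption_motifs: tuple[str, ...] = ()
    ref_units: int = 0
    normal_max_units: int | None = None
    pathogenic_min_units: int | None = None
    inheritance: str = "unknown"
    motif_len: int = 0

    def __post_init__(self):
        if self.end <= self.start:
            raise CatalogError(f"{self.locus_id}: end must exceed start")
        for motif in (self.pathogenic_motifs + self.benign_motifs
                      + self.interruption_motifs):
            if len(motif) < 3 or set(motif) - _BASES:
                raise CatalogError(
                    f"{self.locus_id}: motif {motif!r} must be ACGT-only, "
                    "length >= 3")
        if not self.pathogenic_motifs:
            raise CatalogError(f"{self.locus_id}: needs >=1 pathogenic motif")
        if self.ref_units < 0:
            raise CatalogError(f"{self.locus_id}: ref_units < 0")
        if (self.normal_max_units is not None
                and self.pathogenic_min_units is not None
                and self.pathogenic_min_units <= self.normal_max_units):
            raise CatalogError(
                f"{self.locus_id}: pathogenic_min_units must exceed "
                "normal_max_units")
        if self.inheritance not in _INHERITANCE:
            raise CatalogError(
                f"{self.locus_id}: inheritance {self.inheritance!r} not in "
                f"{sorted(_INHERITANCE)}")
        if self.motif_len != len(self.primary_motif):
            raise CatalogError(
                f"{self.locus_id}: motif_len {self.motif_len} != primary "
                f"motif length {len(self.primary_motif)}")

    @property
    def primary_motif(self) -> str:
        return self.pathogenic_motifs[0]

    @property
    def ref_motif(self) -> str:
        """Motif composing the reference (normal-population) tract: the
        first benign motif where one is catalogued (e.g. AAAAG at RFC1,
        TTTTA at SAMD12 — normal alleles carry the benign unit), else the
        primary pathogenic motif (CAG at HTT and most coding loci)."""
        return self.benign_motifs[0] if self.benign_motifs \
            else self.pathogenic_motifs[0]

    @property
    def tract_len(self) -> int:
        return self.end - self.start

    @property
    def all_motifs(self) -> tuple[str, ...]:
        """Pathogenic, benign then interruption motifs, deduplicated."""
        seen: dict[str, None] = {}
        for m in (self.pathogenic_motifs + self.benign_motifs
                  + self.interruption_motifs):
            seen.setdefault(m)
        return tuple(seen)


@dataclass(frozen=True)
class SnpTarget:
    """A disease-linked SNP enriched alongside the repeat loci."""

    snp_id: str
    chrom: str
    pos: int            # 1-based, as in VCF-style annotation
    ref_allele: str
    alt_allele: str
    linked_disease: str = ""
    window_bp: int = 40_000

    def __post_init__(self):
        if self.window_bp <= 0:
            raise CatalogError(f"{self.snp_id}: window_bp must be positive")
        if self.ref_allele == self.alt_allele:
            raise CatalogError(f"{self.snp_id}: ref and alt alleles equal")
        for a in (self.ref_allele, self.alt_allele):
            if len(a) != 1 or a not in _BASES:
                raise CatalogError(f"{self.snp_id}: alleles must be one base")


@dataclass(frozen=True)
class Catalog:
    loci: tuple[RepeatLocus, ...]
    snps: tuple[SnpTarget, ...] = ()
    genome_size_bp: int = GRCH38_PRIMARY_BP

    def __post_init__(self):
        if not self.loci:
            raise CatalogError("no loci")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate locus_id: {', '.join(dupes)}")
        object.__setattr__(
            self, "loci",
            tuple(sorted(self.loci, key=lambda l: (l.chrom, l.start))))

    def __iter__(self):
        return iter(self.loci)

    def __len__(self):
        return len(self.loci)

    def get(self, locus_id: str) -> RepeatLocus:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(l.locus_id for l in self.loci)


# ---------------------------------------------------------------------------
# parsing

def _opt_int(value: str, line_no: int, col: str) -> int | None:
    value = value.strip()
    if value in ("", "NA", "None", "."):
        return None
    try:
        return int(value)
    except ValueError:
        raise CatalogError(f"line {line_no}: column {col!r} is not an "
                           f"integer: {value!r}") from None


def _motifs(value: str) -> tuple[str, ...]:
    return tuple(m.strip().upper() for m in value.split(",") if m.strip())


def _locus_from_record(rec: dict, line_no: int) -> RepeatLocus:
    missing = [c for c in _CATALOG_COLUMNS if c not in rec]
    if missing:
        raise CatalogError(f"line {line_no}: missing columns {missing}")
    try:
        return RepeatLocus(
            locus_id=str(rec["locus_id"]).strip(),
            gene=str(rec["gene"]).strip(),
            disease=str(rec["disease"]).strip(),
            chrom=str(rec["chrom"]).strip(),
            start=int(rec["start"]),
            end=int(rec["end"]),
            pathogenic_motifs=_motifs(str(rec["pathogenic_motifs"])),
            benign_motifs=_motifs(str(rec.get("benign_motifs") or "")),
            interruption_motifs=_motifs(str(rec.get("interruption_motifs") or "")),
            ref_units=int(rec["ref_units"]),
            normal_max_units=_opt_int(str(rec.get("normal_max_units") or ""),
                                      line_no, "normal_max_units"),
            pathogenic_min_units=_opt_int(str(rec.get("pathogenic_min_units") or ""),
                                          line_no, "pathogenic_min_units"),
            inheritance=str(rec.get("inheritance") or "unknown").strip(),
            motif_len=int(rec["motif_len"]),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, CatalogError):
            raise
        raise CatalogError(f"line {line_no}: malformed row ({exc})") from exc


def _read_tsv(path: Path, columns: Sequence[str]) -> list[tuple[dict, int]]:
    lines = path.read_text().splitlines()
    if not lines:
        raise CatalogError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    records = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise CatalogError(
                f"{path}: line {i}: expected {len(header)} fields, "
                f"got {len(fields)}")
        records.append((dict(zip(header, fields)), i))
    return records


def load_catalog(path: str | Path,
                 snp_path: str | Path | None = None,
                 genome_size_bp: int = GRCH38_PRIMARY_BP) -> Catalog:
    """Load and validate a catalog from TSV (or JSON with keys loci/snps).

    TSV columns are exactly ``locus_id, gene, disease, chrom, start, end,
    pathogenic_motifs, benign_motifs, interruption_motifs, ref_units,
    normal_max_units, pathogenic_min_units, inheritance, motif_len`` with
    comma-joined motif lists.  SNP targets live in a second TSV
    (``snp_path``) or under the ``snps`` key of a JSON catalog.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        loci = [_locus_from_record(rec, i + 1)
                for i, rec in enumerate(doc.get("loci", []))]
        snps = [SnpTarget(**rec) for rec in doc.get("snps", [])]
        return Catalog(tuple(loci), tuple(snps),
                       doc.get("genome_size_bp", genome_size_bp))
    loci = [_locus_from_record(rec, ln) for rec, ln in
            _read_tsv(path, _CATALOG_COLUMNS)]
    snps: list[SnpTarget] = []
    if snp_path is not None:
        for rec, ln in _read_tsv(Path(snp_path), _SNP_COLUMNS):
            try:
                snps.append(SnpTarget(
                    snp_id=rec["snp_id"], chrom=rec["chrom"],
                    pos=int(rec["pos"]), ref_allele=rec["ref_allele"],
                    alt_allele=rec["alt_allele"],
                    linked_disease=rec.get("linked_disease", ""),
                    window_bp=int(rec["window_bp"])))
            except (KeyError, ValueError) as exc:
                raise CatalogError(f"{snp_path}: line {ln}: {exc}") from exc
    return Catalog(tuple(loci), tuple(snps), genome_size_bp)


def load_default_catalog() -> Catalog:
    """The shipped 13-locus catalog (12 classic repeat-disease loci plus the
    polymorphic TNRC6A pentanucleotide locus) and the SCA31-linked SNP."""
    data = Path(__file__).parent / "data"
    return load_catalog(data / "default_catalog.tsv",
                        data / "default_snps.tsv")


def save_catalog(catalog: Catalog, path: str | Path,
                 snp_path: str | Path | None = None) -> None:
    """Write a catalog back to the TSV schema (round-trips with load)."""
    rows = ["\t".join(_CATALOG_COLUMNS)]
    for l in catalog.loci:
        rows.append("\t".join([
            l.locus_id, l.gene, l.disease, l.chrom, str(l.start), str(l.end),
            ",".join(l.pathogenic_motifs), ",".join(l.benign_motifs),
            ",".join(l.interruption_motifs), str(l.ref_units),
            "" if l.normal_max_units is None else str(l.normal_max_units),
            "" if l.pathogenic_min_units is None else str(l.pathogenic_min_units),
            l.inheritance, str(l.motif_len)]))
    Path(path).write_text("\n".join(rows) + "\n")
    if snp_path is not None:
        rows = ["\t".join(_SNP_COLUMNS)]
        for s in catalog.snps:
            rows.append("\t".join([s.snp_id, s.chrom, str(s.pos),
                                   s.ref_allele, s.alt_allele,
                                   s.linked_disease, str(s.window_bp)]))
        Path(snp_path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# target-region design

def merge_intervals(intervals: Iterable[tuple[str, int, int]]
                    ) -> list[tuple[str, int, int]]:
    """Sort and merge 0-based half-open intervals per contig (idempotent)."""
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def make_target_bed(catalog: Catalog,
                    window_bp: int = 100_000,
                    window_mode: str = "total",
                    contig_sizes: dict[str, int] | None = None,
                    ) -> list[tuple[str, int, int, str]]:
    """Build the adaptive-sampling target BED: one enrichment window per
    repeat locus plus one per SNP target.

    ``window_mode="total"`` (default) centers a window of *total* width
    ``window_bp`` on the repeat tract — the reading that reproduces a 0.2%
    genome fraction for a 59-locus panel; ``"flank"`` instead pads
    ``window_bp`` on each side.  Windows are clipped at contig bounds when
    ``contig_sizes`` is given, sorted, and overlapping windows merged
    (merged names are comma-joined).  Returns BED rows
    ``(chrom, start, end, name)``.
    """
    if window_mode not in ("total", "flank"):
        raise ValueError(f"unknown window_mode {window_mode!r}")
    raw: list[tuple[str, int, int, str]] = []
    for locus in catalog.loci:
        if window_mode == "total":
            if window_bp < locus.tract_len:
                raise CatalogError(
                    f"{locus.locus_id}: tract ({locus.tract_len} bp) longer "
                    f"than window ({window_bp} bp)")
            pad = (window_bp - locus.tract_len) // 2
            start = locus.start - pad
            end = start + window_bp
        else:
            start = locus.start - window_bp
            end = locus.end + window_bp
        raw.append((locus.chrom, start, end, locus.locus_id))
    for snp in catalog.snps:
        center = snp.pos - 1
        start = center - snp.window_bp // 2
        raw.append((snp.chrom, start, start + snp.window_bp, snp.snp_id))
    clipped = []
    for chrom, start, end, name in raw:
        start = max(0, start)
        if contig_sizes and chrom in contig_sizes:
            end = min(end, contig_sizes[chrom])
        clipped.append((chrom, start, end, name))
    # merge while concatenating names
    merged: list[list] = []
    for chrom, start, end, name in sorted(clipped):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
            merged[-1][3] += "," + name
        else:
            merged.append([chrom, start, end, name])
    return [tuple(row) for row in merged]


def write_bed(records: Sequence[tuple], path: str | Path) -> None:
    """Serialize BED rows as 6-column BED (score 0, strand '.')."""
    with open(path, "w") as fh:
        for rec in records:
            chrom, start, end = rec[:3]
            name = rec[3] if len(rec) > 3 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t.\n")


def target_fraction(bed: Iterable[tuple],
                    genome_size_bp: int = GRCH38_PRIMARY_BP) -> float:
    """Fraction of the genome covered by the (merged) target BED."""
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    total = sum(rec[2] - rec[1] for rec in bed)
    return total / genome_size_bp
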