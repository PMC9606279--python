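"""End-to-end orchestration: genotype -> prioritize -> decompose ->
evaluate (-> methylation, QC), with all intermediate tables written out.

The pipeline consumes aligned reads (SAM/BAM) plus a locus catalog and a
control-cohort table and produces a triage report: the prioritized locus
list, two-allele genotypes, motif compositions of the top-ranked loci, a
verdict per locus, and a one-line summary per patient.  Every stage is a
thin call into the corresponding library module; the in-memory variant
(`run_sample`) is what the simulation-driven validation uses.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import catalog as cat
from . import decomposer, evaluator, genotyper, methylation as meth, qc
from .catalog import Catalog
from .evaluator import TriageCall, TriageReport, build_report
from .genotyper import LocusGenotype, ReadRepeatMeasurement
from .prioritizer import ControlTable, RankedLocus, build_control_table, \
    rank_loci, ranked_to_frame
from .simulate import SimResult

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_sample", "SampleResult"]

#: reads per allele used for consensus building (more adds little for
#: unit counting and slows pairwise alignment quadratically)
MAX_CONSENSUS_READS = 8


@dataclass
class PipelineConfig:
    catalog_path: str
    alignments: str
    controls_path: str
    out_dir: str
    snp_path: str | None = None
    meth_path: str | None = None
    patient_id: str = "sample"
    anchor_bp: int = 100
    min_support: int = 3
    min_mapq: int = 1
    top_k: int = 20
    window_bp: int = 100_000
    decompose: bool = True
    run_methylation: bool = False
    run_qc: bool = True
    seed: int = 0

    def validate(self) -> None:
        for label, p in (("catalog", self.catalog_path),
                         ("alignments", self.alignments),
                         ("controls", self.controls_path)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.min_support < 1 or self.anchor_bp < 0 or self.top_k < 1:
            raise ValueError("parameters out of range")


@dataclass
class SampleResult:
    report: TriageReport
    ranked: list[RankedLocus]
    genotypes: dict[str, LocusGenotype]
    measurements: list[ReadRepeatMeasurement]
    compositions: dict[str, decomposer.MotifDecomposition] = field(
        default_factory=dict)
    interruptions: dict[str, list] = field(default_factory=dict)
    meth_calls: list = field(default_factory=list)

    @property
    def causal_rank(self) -> dict[str, int]:
        return {r.locus_id: r.rank for r in self.ranked}


def _decompose_top(ranked: Sequence[RankedLocus],
                   genotypes: dict[str, LocusGenotype],
                   measurements: Iterable[ReadRepeatMeasurement],
                   catalog: Catalog, top_k: int):
    """Consensus + motif decomposition of the larger allele for the
    ``top_k`` ranked loci with a determined genotype."""
    by_read = {}
    for m in measurements:
        if m.spans_tract and m.tract_sequence:
            by_read[(m.locus_id, m.read_id)] = m
    compositions: dict[str, decomposer.MotifDecomposition] = {}
    interruptions: dict[str, list] = {}
    for r in ranked[:top_k]:
        g = genotypes.get(r.locus_id)
        if g is None or g.undetermined:
            continue
        locus = catalog.get(r.locus_id)
        large_reads = g.supporting_reads[1]
        records = []
        for rid in sorted(large_reads):
            m = by_read.get((r.locus_id, rid))
            if m is None:
                continue
            seq = m.tract_sequence
            records.append((rid, seq))
        if not records:
            continue
        records = records[:MAX_CONSENSUS_READS]
        cons = decomposer.build_consensus(records, r.locus_id, 1)
        dec = decomposer.decompose_motifs(cons.sequence, locus.all_motifs)
        compositions[r.locus_id] = dec
        interruptions[r.locus_id] = decomposer.detect_interruptions(dec,
                                                                    locus)
    return compositions, interruptions


def run_sample(measurements: list[ReadRepeatMeasurement],
               controls: pd.DataFrame | ControlTable,
               catalog: Catalog,
               patient_id: str = "sample",
               min_support: int = 3,
               top_k: int = 20,
               decompose: bool = True,
               meth_table: pd.DataFrame | None = None) -> SampleResult:
    """In-memory pipeline core shared by the CLI and the simulations."""
    if not isinstance(controls, ControlTable):
        controls = build_control_table(controls, catalog)
    genotypes = genotyper.genotype_all(measurements, catalog, min_support)
    ranked = rank_loci(measurements, controls, catalog, min_support)
    compositions: dict = {}
    interruptions: dict = {}
    if decompose:
        compositions, interruptions = _decompose_top(
            ranked, genotypes, measurements, catalog, top_k)
    calls: list[TriageCall] = []
    for r in ranked:
        locus = catalog.get(r.locus_id)
        call = evaluator.evaluate_locus(genotypes[r.locus_id],
                                        compositions.get(r.locus_id),
                                        locus)
        calls.append(call)
    report = build_report(patient_id, calls)
    meth_calls = []
    if meth_table is not None:
        for locus_id, g in genotypes.items():
            if g.undetermined:
                continue
            sub = meth_table[meth_table["read_id"].isin(
                g.supporting_reads[0] | g.supporting_reads[1])]
            if sub.empty:
                continue
            meth_calls.extend(meth.allele_methylation(meth_table, g))
    return SampleResult(report, ranked, genotypes, measurements,
                        compositions, interruptions, meth_calls)


def _genotypes_frame(genotypes: dict[str, LocusGenotype]) -> pd.DataFrame:
    rows = []
    for locus_id, g in genotypes.items():
        if g.undetermined:
            rows.append((locus_id, None, None, None, None, False,
                         g.n_spanning, True))
        else:
            rows.append((locus_id, g.allele_units[0], g.allele_units[1],
                         g.allele_copy_change[0], g.allele_copy_change[1],
                         g.homozygous, g.n_spanning, False))
    return pd.DataFrame(rows, columns=[
        "locus_id", "allele1_units", "allele2_units", "allele1_change",
        "allele2_change", "homozygous", "n_spanning", "undetermined"])


def run_pipeline(config: PipelineConfig) -> SampleResult:
    """File-based pipeline: read catalog/alignments/controls, run every
    stage, and write intermediate TSVs plus a JSON report to
    ``config.out_dir``.  Deterministic given the inputs and seeds."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    catalog = cat.load_catalog(config.catalog_path, config.snp_path)
    log.info("stage catalog: %d loci (%.2fs)", len(catalog), time.time() - t0)

    t = time.time()
    measurements = genotyper.measure_alignments(
        config.alignments, catalog, config.anchor_bp, config.min_mapq)
    genotyper.measurements_to_frame(measurements).to_csv(
        out / "measurements.tsv", sep="\t", index=False)
    log.info("stage genotype: %d measurements (%.2fs)", len(measurements),
             time.time() - t)

    controls = pd.read_csv(config.controls_path, sep="\t")
    meth_table = None
    if config.run_methylation and config.meth_path:
        meth_table = pd.read_csv(config.meth_path, sep="\t")
    result = run_sample(measurements, controls, catalog,
                        patient_id=config.patient_id,
                        min_support=config.min_support,
                        top_k=config.top_k,
                        decompose=config.decompose,
                        meth_table=meth_table)

    _genotypes_frame(result.genotypes).to_csv(out / "genotypes.tsv",
                                              sep="\t", index=False)
    ranked_to_frame(result.ranked).to_csv(out / "ranked.tsv", sep="\t",
                                          index=False)
    comp_rows = []
    for locus_id, dec in result.compositions.items():
        for motif, count in sorted(dec.composition.items()):
            comp_rows.append((locus_id, motif, count, dec.other_bp))
    pd.DataFrame(comp_rows, columns=[
        "locus_id", "motif", "units", "other_bp"]).to_csv(
        out / "compositions.tsv", sep="\t", index=False)
    call_rows = [(c.locus_id, c.verdict, ";".join(c.rationale),
                  c.allele_units, c.pathogenic_motif_units)
                 for c in result.report.calls]
    pd.DataFrame(call_rows, columns=[
        "locus_id", "verdict", "rationale", "allele_units",
        "pathogenic_motif_units"]).to_csv(out / "calls.tsv", sep="\t",
                                          index=False)
    report_doc = {
        "patient_id": result.report.patient_id,
        "summary": result.report.summary,
        "multiple_hits": result.report.multiple_hits,
        "calls": [
            {"locus_id": c.locus_id, "verdict": c.verdict,
             "rationale": list(c.rationale),
             "allele_units": list(c.allele_units) if c.allele_units else None,
             "pathogenic_motif_units": c.pathogenic_motif_units}
            for c in result.report.calls],
    }
    (out / "report.json").write_text(json.dumps(report_doc, indent=2,
                                                sort_keys=True) + "\n")
    if config.run_qc:
        try:
            import pysam
            with pysam.AlignmentFile(config.alignments,
                                     check_sq=False) as sam:
                sizes = dict(zip(sam.references, sam.lengths))
            bed = cat.make_target_bed(catalog, config.window_bp,
                                      contig_sizes=sizes)
            stats = qc.coverage_stats(config.alignments, bed)
            (out / "qc.json").write_text(
                json.dumps(stats.summary(), indent=2, sort_keys=True) + "\n")
        except (ValueError, cat.CatalogError) as exc:
            log.warning("stage qc skipped: %s", exc)
    log.info("pipeline done in %.2fs: %s", time.time() - t0,
             result.report.summary)
    return result


def run_validation_cohort(seed: int = 0, depth: float = 20.0,
                          n_controls: int = 27, jitter_units: int = 3,
                          confounders: bool = True,
                          catalog: Catalog | None = None) -> pd.DataFrame:
    """Re-run the 12-patient validation study in silico.

    Each confirmed genotype is simulated on the 13-locus mini-genome at the
    given spanning depth with default error rates (plus the two observed
    confounders: a benign TNRC6A expansion and a heterozygous RFC1
    expansion), prioritized against a simulated 27-control cohort, and the
    causal locus's rank and triage verdict recorded.
    """
    from . import fixtures
    from .simulate import SimSpec, simulate_controls, simulate_reads

    if catalog is None:
        catalog = cat.load_default_catalog()
    rows = []
    for i, patient in enumerate(fixtures.load_validation_fixture()):
        spec = SimSpec(catalog=catalog,
                       alleles=fixtures.allele_specs_for(patient,
                                                         confounders),
                       depth=depth, seed=seed * 1000 + i)
        sim = simulate_reads(spec)
        controls = simulate_controls(sim.genome.catalog, n=n_controls,
                                     jitter_units=jitter_units,
                                     seed=seed * 1000 + 500 + i)
        sr = run_sample(measure_simulated(sim), controls, sim.genome.catalog,
                        patient_id=patient.patient_id)
        causal = next(c for c in sr.report.calls
                      if c.locus_id == patient.locus_id)
        rows.append((patient.patient_id, patient.locus_id,
                     sr.causal_rank[patient.locus_id], causal.verdict,
                     sr.report.summary))
    return pd.DataFrame(rows, columns=[
        "patient_id", "causal_locus", "causal_rank", "causal_verdict",
        "summary"])


def measure_simulated(result: SimResult, anchor_bp: int = 100,
                      min_mapq: int = 1) -> list[ReadRepeatMeasurement]:
    """Measure a simulation's reads directly (no SAM round-trip); each
    mini-genome contig hosts exactly one locus."""
    catalog = result.genome.catalog
    by_contig = {l.chrom: l for l in catalog.loci}
    out = []
    for aln in result.to_alignments():
        locus = by_contig.get(aln.reference_name)
        if locus is None:
            continue
        m = genotyper.measure_read_copy_change(aln, locus, anchor_bp,
                                               min_mapq)
        if m is not None:
            out.append(m)
    return out
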