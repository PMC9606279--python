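"""Simulator: mini-genomes, ground-truth reads, controls, methylation."""

import numpy as np
import pytest

from tandemtriage.catalog import Catalog, RepeatLocus
from tandemtriage.pipeline import measure_simulated
from tandemtriage.simulate import (AlleleSpec, MotifMiscall, SimSpec,
                                   build_mini_genome, simulate_controls,
                                   simulate_methylation, simulate_reads,
                                   reverse_complement)


def _cstb_catalog():
    locus = RepeatLocus(
        locus_id="CSTB", gene="CSTB", disease="ULD", chrom="chr21",
        start=43_776_442, end=43_776_478,
        pathogenic_motifs=("CCCCGCCCCGCG",), ref_units=3,
        normal_max_units=3, pathogenic_min_units=30, inheritance="AR",
        motif_len=12)
    return Catalog((locus,))


class TestMiniGenome:
    def test_contig_length_is_flanks_plus_tract(self):
        g = build_mini_genome(_cstb_catalog(), flank_bp=2000, seed=0)
        assert len(g.contigs["CSTB"]) == 2000 + 3 * 12 + 2000

    def test_rebased_tract_coordinates(self):
        g = build_mini_genome(_cstb_catalog(), flank_bp=2000, seed=0)
        locus = g.catalog.get("CSTB")
        assert (locus.start, locus.end) == (2000, 2036)
        assert g.contigs["CSTB"][2000:2036] == "CCCCGCCCCGCG" * 3

    def test_small_flank_rejected(self):
        with pytest.raises(ValueError):
            build_mini_genome(_cstb_catalog(), flank_bp=0)

    def test_same_seed_identical_fasta(self, tmp_path):
        for i in (1, 2):
            g = build_mini_genome(_cstb_catalog(), flank_bp=2000, seed=42)
            g.write_fasta(tmp_path / f"g{i}.fa")
        assert (tmp_path / "g1.fa").read_bytes() == \
            (tmp_path / "g2.fa").read_bytes()


class TestSimulateReads:
    def test_errorfree_cigar_net_insertion_exact(self, het_rfc1_sim):
        result, measurements = het_rfc1_sim
        truth = {r.read_id: r for r in result.reads}
        spanning = [m for m in measurements if m.spans_tract]
        assert spanning
        for m in spanning:
            t = truth[m.read_id]
            expected = (622 - 11) * 5 if t.allele_index == 1 else 0
            assert m.net_bp_change == expected
            assert m.copy_change == t.true_copy_change

    def test_determinism_same_seed(self, rfc1_catalog, tmp_path):
        spec = dict(catalog=rfc1_catalog,
                    alleles={"RFC1": (AlleleSpec.simple("AAAAG", 11),
                                      AlleleSpec.simple("AAGGG", 100))},
                    depth=6, seed=99)
        for i in (1, 2):
            r = simulate_reads(SimSpec(**spec))
            r.write_fastq(tmp_path / f"r{i}.fastq")
            r.write_sam(tmp_path / f"r{i}.sam")
        assert (tmp_path / "r1.fastq").read_bytes() == \
            (tmp_path / "r2.fastq").read_bytes()
        assert (tmp_path / "r1.sam").read_bytes() == \
            (tmp_path / "r2.sam").read_bytes()

    def test_read_sam_truth_counts_match(self, het_rfc1_sim, tmp_path):
        result, _ = het_rfc1_sim
        fastq = tmp_path / "r.fastq"
        sam = tmp_path / "r.sam"
        result.write_fastq(fastq)
        result.write_sam(sam)
        n_fastq = fastq.read_text().count("@RFC1")
        n_sam = sum(1 for line in sam.read_text().splitlines()
                    if not line.startswith("@"))
        assert n_fastq == n_sam == len(result.reads) \
            == len(result.truth_table())

    def test_spanning_depth_near_request(self, het_rfc1_sim):
        result, _ = het_rfc1_sim
        n_span = sum(1 for r in result.reads if r.spans_tract)
        assert 0.7 * 20 <= n_span <= 1.3 * 20

    def test_strand_specific_miscall(self, rfc1_catalog):
        spec = SimSpec(
            catalog=rfc1_catalog,
            alleles={"RFC1": (AlleleSpec.simple("AAGGG", 200),
                              AlleleSpec.simple("AAGGG", 200))},
            depth=12, sub_rate=0, ins_rate=0, del_rate=0,
            motif_miscall=MotifMiscall("AAGGG", "AAGG", 0.3, "-"), seed=8)
        result = simulate_reads(spec)
        from tandemtriage.decomposer import decompose_motifs
        for m in measure_simulated(result):
            if not m.spans_tract:
                continue
            dec = decompose_motifs(m.tract_sequence, ["AAGGG", "AAGG"])
            n_corrupt = dec.composition.get("AAGG", 0)
            if m.strand == "-":
                assert n_corrupt > 0
            else:
                assert n_corrupt == 0

    def test_minus_strand_fastq_is_reverse_complement(self, het_rfc1_sim):
        result, _ = het_rfc1_sim
        minus = next(r for r in result.reads if r.strand == "-")
        assert minus.fastq_seq == reverse_complement(minus.seq)

    def test_realized_length_near_lognormal_mean(self, rfc1_catalog):
        spec = SimSpec(catalog=rfc1_catalog, alleles={}, depth=250,
                       read_len_mean=12_000, read_len_sigma=0.25,
                       flank_bp=20_000, offtarget_fraction=0.0, seed=5)
        result = simulate_reads(spec)
        lengths = [len(r.seq) for r in result.reads]
        assert len(lengths) >= 200
        assert abs(np.mean(lengths) - 12_000) / 12_000 < 0.10

    def test_zero_depth_warns_not_raises(self, rfc1_catalog):
        result = simulate_reads(SimSpec(catalog=rfc1_catalog, alleles={},
                                        depth=0.4, seed=1))
        assert result.warnings
        assert "zero spanning" in result.warnings[0]


class TestControls:
    def test_27_controls_give_54_alleles_within_jitter(self, default_catalog):
        df = simulate_controls(default_catalog, n=27, jitter_units=3, seed=4)
        for locus in default_catalog:
            sub = df[df["locus_id"] == locus.locus_id]
            assert len(sub) == 54
            assert sub["allele_units"].between(
                max(0, locus.ref_units - 3), locus.ref_units + 3).all()

    def test_zero_jitter_all_reference(self, default_catalog):
        df = simulate_controls(default_catalog, n=5, jitter_units=0, seed=4)
        assert (df["copy_change"] == 0).all()

    def test_no_controls_rejected(self, default_catalog):
        with pytest.raises(ValueError):
            simulate_controls(default_catalog, n=0)


@pytest.fixture(scope="module")
def ggc_sim():
    locus = RepeatLocus(
        locus_id="NOTCH2NLC", gene="NOTCH2NLC", disease="NIID",
        chrom="chr1", start=149_390_802, end=149_390_841,
        pathogenic_motifs=("GGC",), ref_units=13, normal_max_units=39,
        pathogenic_min_units=60, inheritance="AD", motif_len=3)
    spec = SimSpec(
        catalog=Catalog((locus,)),
        alleles={"NOTCH2NLC": (AlleleSpec.simple("GGC", 20),
                               AlleleSpec.simple("GGC", 500))},
        depth=12, seed=21)
    return simulate_reads(spec)


class TestMethylation:
    def test_emitted_probs_near_profile(self, ggc_sim):
        table = simulate_methylation(ggc_sim, {"NOTCH2NLC": (0.05, 0.9)},
                                     seed=3)
        truth = {r.read_id: r.allele_index for r in ggc_sim.reads}
        table["allele"] = table["read_id"].map(truth)
        means = table.groupby("allele")["prob"].mean()
        counts = table.groupby("allele").size()
        assert (counts >= 50).all()
        assert abs(means[0] - 0.05) <= 0.1
        assert abs(means[1] - 0.9) <= 0.1

    def test_zero_profile_stays_low(self, ggc_sim):
        table = simulate_methylation(ggc_sim, {"NOTCH2NLC": (0.0, 0.0)},
                                     seed=3)
        assert (table["prob"] <= 0.2).all()

    def test_no_cpg_empty_table(self, rfc1_catalog):
        # AAAAG/TTTTA-style tracts and AT-rich flanks can lack CpGs only in
        # the tract; restrict to a tract-only check via a tiny contig
        spec = SimSpec(catalog=rfc1_catalog, alleles={}, depth=2, seed=2)
        result = simulate_reads(spec)
        for read in result.reads:
            read.seq = read.seq.replace("CG", "CT")
        table = simulate_methylation(result, {"RFC1": (0.5, 0.5)}, seed=1)
        assert table.empty
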