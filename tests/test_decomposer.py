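"""Consensus, motif decomposition (vs exhaustive oracle), waterfall,
interruptions."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tandemtriage.catalog import RepeatLocus
from tandemtriage.decomposer import (OTHER, build_consensus,
                                     decompose_motifs, detect_interruptions,
                                     waterfall_from_measurements,
                                     waterfall_matrix)
from tandemtriage.pipeline import measure_simulated
from tandemtriage.simulate import (AlleleSpec, MotifMiscall, SimSpec,
                                   reverse_complement, simulate_reads)


def brute_force_min_cost(seq, motifs, max_mismatch=1):
    """Exhaustive enumeration of all segmentations (reference oracle)."""
    best = [len(seq) + 1]

    def rec(i, cost):
        if cost >= best[0]:
            return
        if i == len(seq):
            best[0] = cost
            return
        rec(i + 1, cost + 1)  # OTHER base
        for m in motifs:
            L = len(m)
            if i + L <= len(seq):
                mm = sum(a != b for a, b in zip(seq[i:i + L], m))
                limit = max_mismatch if L >= 4 else 0
                if mm <= limit:
                    rec(i + L, cost + mm)

    rec(0, 0)
    return best[0]


def _cost(dec):
    return sum(u.mismatches for u in dec.units if u.label != OTHER) \
        + dec.other_bp


class TestConsensus:
    def test_identical_copies(self):
        cons = build_consensus(["TGGAA" * 10] * 5)
        assert cons.sequence == "TGGAA" * 10
        assert cons.n_reads_used == 5

    def test_single_read(self):
        cons = build_consensus([("only", "CAGCAG")])
        assert cons.sequence == "CAGCAG"
        assert cons.medoid_read_id == "only"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])

    @pytest.mark.parametrize("seed", range(5))
    def test_substitution_recovery(self, seed):
        """7 reads of (CAG)42 at 1% substitutions polish back exactly."""
        rng = np.random.default_rng(seed)
        truth = "CAG" * 42
        reads = []
        for i in range(7):
            s = list(truth)
            for j in range(len(s)):
                if rng.random() < 0.01:
                    s[j] = "ACGT"[(("ACGT".index(s[j])) + 1 +
                                   int(rng.integers(0, 3))) % 4]
            reads.append((f"r{i}", "".join(s)))
        assert build_consensus(reads).sequence == truth


class TestDecomposeMotifs:
    def test_two_motif_exact(self):
        dec = decompose_motifs("TGGAATGGAATAGAA", ["TGGAA", "TAGAA"])
        assert [u.label for u in dec.units] == ["TGGAA", "TGGAA", "TAGAA"]
        assert dec.other_bp == 0

    def test_interrupted_cag_composition(self):
        dec = decompose_motifs("CAG" * 4 + "CAACAG" + "CCG" * 2,
                               ["CAG", "CAACAG", "CCG"])
        assert dec.composition == {"CAG": 4, "CAACAG": 1, "CCG": 2}

    def test_mismatch_tolerant_unit(self):
        seq = "TGGAATGGTATGGAA"
        dec = decompose_motifs(seq, ["TGGAA", "TAGAA"])
        labels = [(u.label, u.mismatches) for u in dec.units]
        assert labels == [("TGGAA", 0), ("TGGAA", 1), ("TGGAA", 0)]
        assert _cost(dec) == brute_force_min_cost(seq, ["TGGAA", "TAGAA"])

    def test_short_motifs_no_mismatch_tolerance(self):
        # a 1-mismatch CAG would match nearly anything; must be OTHER
        dec = decompose_motifs("TTT", ["CAG"])
        assert dec.other_bp == 3

    def test_empty_motifs_rejected(self):
        with pytest.raises(ValueError):
            decompose_motifs("ACGT", [])

    @pytest.mark.parametrize("motifs", [["TGGAA", "TAGAA"],
                                        ["CAG", "CAACAG"],
                                        ["AAGGG", "AAGG"]])
    def test_matches_exhaustive_oracle(self, motifs):
        rng = np.random.default_rng(hash(tuple(motifs)) % 2**31)
        for _ in range(120):
            n = int(rng.integers(0, 31))
            seq = "".join(rng.choice(list("ACGT"), size=n)) if n else ""
            dec = decompose_motifs(seq, motifs)
            assert _cost(dec) == brute_force_min_cost(seq, motifs)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=0, max_size=40))
    def test_partition_invariant(self, seq):
        dec = decompose_motifs(seq, ["TGGAA", "CAG"])
        assert "".join(seq[u.start:u.end] for u in dec.units) == seq.upper()
        labeled_bp = sum(u.end - u.start for u in dec.units
                         if u.label != OTHER)
        assert labeled_bp + dec.other_bp == len(seq)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=0, max_size=40))
    def test_reverse_complement_composition_invariant(self, seq):
        motifs = ["TGGAA", "TAGAA"]
        fwd = decompose_motifs(seq, motifs)
        rev = decompose_motifs(reverse_complement(seq),
                               [reverse_complement(m) for m in motifs])
        assert {reverse_complement(k): v
                for k, v in rev.composition.items()
                if k != OTHER} == {k: v for k, v in fwd.composition.items()
                                   if k != OTHER}
        assert rev.other_bp == fwd.other_bp


class TestWaterfall:
    def test_two_allele_row_groups(self):
        reads = [(f"s{i}", "GGC" * 19, "+") for i in range(5)] + \
                [(f"l{i}", "GGC" * 185, "+") for i in range(5)]
        rows = waterfall_matrix(reads, ["GGC"])
        counts = sorted(collections.Counter(
            len([l for l in labels if l == "GGC"])
            for _, _, labels in rows).items())
        assert counts == [(19, 5), (185, 5)]
        # longest expansions sort to the top
        assert rows[0][0].startswith("l")

    def test_empty(self):
        assert waterfall_matrix([], ["GGC"]) == []

    def test_minus_strand_reoriented(self):
        seq = "TGGAA" * 4
        rows = waterfall_matrix([("r", reverse_complement(seq), "-")],
                                ["TGGAA"])
        assert rows[0][2] == ["TGGAA"] * 4

    def test_miscall_artifact_on_minus_rows(self, rfc1_catalog):
        spec = SimSpec(
            catalog=rfc1_catalog,
            alleles={"RFC1": (AlleleSpec.simple("AAGGG", 200),
                              AlleleSpec.simple("AAGGG", 200))},
            depth=14, sub_rate=0, ins_rate=0, del_rate=0,
            motif_miscall=MotifMiscall("AAGGG", "AAGG", 0.3, "-"), seed=6)
        result = simulate_reads(spec)
        ms = [m for m in measure_simulated(result) if m.spans_tract]
        rows = waterfall_from_measurements(ms, ["AAGGG", "AAGG"])
        per_strand = {"+": [], "-": []}
        for _, strand, labels in rows:
            per_strand[strand].append(
                sum(1 for l in labels if l == "AAGG"))
        assert per_strand["+"] and per_strand["-"]
        assert max(per_strand["+"]) == 0
        assert min(per_strand["-"]) > 0


class TestInterruptions:
    htt = RepeatLocus(
        locus_id="HTT", gene="HTT", disease="HD", chrom="chr4",
        start=3_074_876, end=3_074_939, pathogenic_motifs=("CAG",),
        interruption_motifs=("CAACAG", "CCG"), ref_units=21,
        normal_max_units=26, pathogenic_min_units=36, inheritance="AD",
        motif_len=3)
    sca8 = RepeatLocus(
        locus_id="ATXN8OS", gene="ATXN8OS", disease="SCA8", chrom="chr13",
        start=70_139_383, end=70_139_428, pathogenic_motifs=("CTG",),
        benign_motifs=("CTA",), interruption_motifs=("CCG",), ref_units=15,
        normal_max_units=40, pathogenic_min_units=71, inheritance="AD",
        motif_len=3)

    def test_terminal_caacag(self):
        dec = decompose_motifs("CAG" * 42 + "CAACAG", self.htt.all_motifs)
        calls = detect_interruptions(dec, self.htt)
        assert len(calls) == 1
        assert (calls[0].motif, calls[0].n_units, calls[0].position) == \
            ("CAACAG", 1, "3prime")

    def test_pure_tract_no_calls(self):
        dec = decompose_motifs("CAG" * 42, self.htt.all_motifs)
        assert detect_interruptions(dec, self.htt) == []

    def test_benign_block_5prime_of_pathogenic(self):
        dec = decompose_motifs("CTA" * 9 + "CTG" * 86, self.sca8.all_motifs)
        calls = detect_interruptions(dec, self.sca8)
        assert len(calls) == 1
        call = calls[0]
        assert (call.motif, call.n_units, call.position,
                call.pathogenic_units) == ("CTA", 9, "5prime", 86)

    def test_internal_interruption(self):
        dec = decompose_motifs("CAG" * 10 + "CCG" + "CAG" * 10,
                               self.htt.all_motifs)
        calls = detect_interruptions(dec, self.htt)
        assert [c.position for c in calls] == ["internal"]
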