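"""Packaged validation-cohort fixture.

Twelve genetically confirmed repeat-expansion patients (the validation
arm: one per classic locus, unit counts as confirmed by conventional
testing) and ten discovery-arm outcomes, as structured records.  The
fixture drives cohort summaries and the end-to-end simulation: each
validation patient can be turned into per-locus allele specs, including
the two known prioritization confounders — a large benign pentanucleotide
expansion at TNRC6A ranking above the small CACNA1A expansion, and a
heterozygous (carrier) RFC1 expansion ranking above the causal DMPK
expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import AlleleSpec

__all__ = [
    "ValidationPatient",
    "DiscoveryOutcome",
    "load_validation_fixture",
    "load_discovery_fixture",
    "allele_specs_for",
]


@dataclass(frozen=True)
class ValidationPatient:
    patient_id: str
    locus_id: str
    gene: str
    motif: str
    allele_units: tuple[int, int]        # pathogenic-motif units, ascending
    benign_units: tuple[int, int] | None  # co-occurring benign-motif units
    rank: int                            # observed prioritization rank
    result: str


@dataclass(frozen=True)
class DiscoveryOutcome:
    patient_id: str
    locus_id: str | None
    allele_units: tuple[int, int] | None
    rank: int | None
    result: str


_VALIDATION = (
    ValidationPatient("P01", "HTT", "HTT", "CAG", (18, 42), None, 1, "HD"),
    ValidationPatient("P02", "ATXN3", "ATXN3", "CAG", (11, 72), None, 1,
                      "SCA3"),
    ValidationPatient("P03", "CACNA1A", "CACNA1A", "CAG", (13, 22), None, 2,
                      "SCA6"),
    ValidationPatient("P04", "DMPK", "DMPK", "CTG", (29, 95), None, 2, "MyD"),
    ValidationPatient("P05", "ATXN8OS", "ATXN8OS/ATXN8", "CTG", (86, 168),
                      (9, 11), 1, "SCA8"),
    ValidationPatient("P06", "NOTCH2NLC", "NOTCH2NLC", "GGC", (19, 185),
                      None, 1, "NIID"),
    ValidationPatient("P07", "PHOX2B", "PHOX2B", "GCA", (19, 26), None, 1,
                      "CCHS"),
    ValidationPatient("P08", "SAMD12", "SAMD12", "TTTCA", (0, 167),
                      (17, 500), 1, "BAFME"),
    ValidationPatient("P09", "RFC1", "RFC1", "AAGGG", (622, 622), None, 1,
                      "CANVAS"),
    ValidationPatient("P10", "BEAN1", "BEAN1", "TGGAA", (0, 373), None, 1,
                      "SCA31"),
    ValidationPatient("P11", "NOP56", "NOP56", "GGCCTG", (10, 1593), None, 1,
                      "SCA36"),
    ValidationPatient("P12", "CSTB", "CSTB", "CCCCGCCCCGCG", (40, 70), None,
                      1, "ULD"),
)

_DISCOVERY = (
    DiscoveryOutcome("P13", "CACNA1A", (16, 21), 1, "SCA6"),
    DiscoveryOutcome("P14", "BEAN1", (0, 249), 1, "SCA31"),
    DiscoveryOutcome("P15", "CACNA1A", (20, 21), 1, "SCA6"),
    DiscoveryOutcome("P16", "BEAN1", (0, 269), 1, "SCA31"),
    DiscoveryOutcome("P17", "ATXN8OS", (12, 47), 1,
                     "intermediate SCA8 expansion, unlikely pathogenic"),
    DiscoveryOutcome("P18", "RFC1", (714, 988), 1, "CANVAS"),
    DiscoveryOutcome("P19", "RFC1", (682, 927), 1, "CANVAS"),
    DiscoveryOutcome("P20", None, None, None, "no known repeat expansion"),
    DiscoveryOutcome("P21", None, None, None, "no known repeat expansion"),
    DiscoveryOutcome("P22", None, None, None, "no known repeat expansion"),
)


def load_validation_fixture() -> tuple[ValidationPatient, ...]:
    """The 12 confirmed validation patients (genotype + observed rank)."""
    return _VALIDATION


def load_discovery_fixture() -> tuple[DiscoveryOutcome, ...]:
    """The 10 discovery-arm outcomes."""
    return _DISCOVERY


# per-locus benign reference motifs used when simulating unexpanded alleles
# at loci whose reference tract is not the pathogenic motif
_REF_MOTIF = {"SAMD12": "TTTTA", "BEAN1": "TAAAA", "RFC1": "AAAAG",
              "TNRC6A": "TTTTA"}


def _causal_alleles(p: ValidationPatient) -> tuple[AlleleSpec, AlleleSpec]:
    if p.locus_id == "ATXN8OS":
        # benign CTA block 5' of the pathogenic CTG run on each allele
        b = p.benign_units or (0, 0)
        return (AlleleSpec((("CTA", b[0]), (p.motif, p.allele_units[0]))),
                AlleleSpec((("CTA", b[1]), (p.motif, p.allele_units[1]))))
    if p.locus_id == "SAMD12":
        b = p.benign_units or (0, 0)
        return (AlleleSpec((("TTTTA", b[0]),)),
                AlleleSpec(((p.motif, p.allele_units[1]), ("TTTTA", b[1]))))
    if p.locus_id == "BEAN1":
        # unexpanded allele keeps the benign reference pentanucleotide
        return (AlleleSpec.simple("TAAAA", 13),
                AlleleSpec.simple(p.motif, p.allele_units[1]))
    return (AlleleSpec.simple(p.motif, p.allele_units[0]),
            AlleleSpec.simple(p.motif, p.allele_units[1]))


def allele_specs_for(p: ValidationPatient, confounders: bool = True
                     ) -> dict[str, tuple[AlleleSpec, AlleleSpec]]:
    """Per-locus diploid allele specs for one validation patient.

    With ``confounders`` (the default, matching the observed cohort),
    the SCA6 patient additionally carries a large benign TTTTA expansion
    at TNRC6A and the myotonic-dystrophy patient a heterozygous RFC1
    expansion — the two non-causal loci observed at rank 1.
    """
    specs = {p.locus_id: _causal_alleles(p)}
    if confounders and p.patient_id == "P03":
        specs["TNRC6A"] = (AlleleSpec.simple("TTTTA", 18),
                           AlleleSpec.simple("TTTTA", 118))
    if confounders and p.patient_id == "P04":
        specs["RFC1"] = (AlleleSpec.simple("AAAAG", 11),
                         AlleleSpec.simple("AAGGG", 622))
    return specs
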