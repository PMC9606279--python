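import pytest

from tandemtriage.catalog import Catalog, RepeatLocus, load_default_catalog
from tandemtriage.pipeline import measure_simulated
from tandemtriage.simulate import AlleleSpec, SimSpec, simulate_reads


@pytest.fixture(scope="session")
def default_catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def rfc1_catalog():
    """Single RFC1-like AR pentanucleotide locus, for fast simulations."""
    locus = RepeatLocus(
        locus_id="RFC1", gene="RFC1", disease="CANVAS", chrom="chr4",
        start=39_348_424, end=39_348_479,
        pathogenic_motifs=("AAGGG", "ACAGG"), benign_motifs=("AAAAG",),
        interruption_motifs=(), ref_units=11, normal_max_units=20,
        pathogenic_min_units=400, inheritance="AR", motif_len=5)
    return Catalog((locus,))


@pytest.fixture(scope="session")
def het_rfc1_sim(rfc1_catalog):
    """Error-free heterozygous 11/622-unit simulation plus measurements."""
    spec = SimSpec(
        catalog=rfc1_catalog,
        alleles={"RFC1": (AlleleSpec.simple("AAAAG", 11),
                          AlleleSpec.simple("AAGGG", 622))},
        depth=20, sub_rate=0.0, ins_rate=0.0, del_rate=0.0, seed=13)
    result = simulate_reads(spec)
    measurements = measure_simulated(result)
    return result, measurements
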