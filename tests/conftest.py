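import pytest

from vegfa_splice import (
    ToyLocusSpec,
    build_junction_catalog,
    build_probes,
    default_vegfa_catalog,
    make_toy_locus,
)
from vegfa_splice.locus_model import DEFAULT_ACCEPTORS, DEFAULT_DONORS
from vegfa_splice.synthetic_data import b_isoform_transcripts, canonical_transcripts

TOY_SEED = 1234


@pytest.fixture(scope="session")
def toy_locus():
    return make_toy_locus(ToyLocusSpec(seed=TOY_SEED))


@pytest.fixture(scope="session")
def real_catalog():
    return default_vegfa_catalog()


@pytest.fixture(scope="session")
def toy_junctions(toy_locus):
    """The ten exon-8 junctions on the toy locus."""
    return build_junction_catalog(toy_locus.exons, DEFAULT_DONORS, DEFAULT_ACCEPTORS)


@pytest.fixture(scope="session")
def toy_probes(toy_locus, toy_junctions):
    return build_probes(toy_locus, toy_junctions)


@pytest.fixture(scope="session")
def canonical(toy_locus):
    return canonical_transcripts(toy_locus)


@pytest.fixture(scope="session")
def b_isoforms(toy_locus):
    return b_isoform_transcripts(toy_locus)


@pytest.fixture(scope="session")
def annotation(canonical, b_isoforms):
    """Canonical models plus the 8b-spliced 165b model (the 'genes.gtf' pool)."""
    return {**canonical, "VEGFA_165b": b_isoforms["VEGFA_165b"]}
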