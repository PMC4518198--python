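import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from phenometer import (
    MetaboliteKey,
    Phenotype,
    RunConfig,
    default_scenario,
    generate_library,
    load_default_synonyms,
)


def make_phenotype(pid, responses):
    """Build a phenotype from a plain {name: SIR} dict (unknown keys)."""
    return Phenotype(
        id=pid,
        responses={MetaboliteKey(name, known=False): sir for name, sir in responses.items()},
    )


@pytest.fixture(scope="session")
def synonyms():
    return load_default_synonyms()


@pytest.fixture(scope="session")
def default_library():
    """Default synthetic scenario: 13 genes x 2 alleles, seed 0."""
    sc = default_scenario(seed=0)
    phenotypes, truth, pathway_map = generate_library(sc)
    return phenotypes, truth, pathway_map


@pytest.fixture()
def cfg():
    return RunConfig()
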