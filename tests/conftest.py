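import pytest

from toxscan.synthetic_data import (
    SimulationConfig,
    generate_corpus,
    reference_archetype,
)


@pytest.fixture(scope="session")
def archetype():
    return reference_archetype()


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic preset: 200 genomes, divergence 0.3, seed 7."""
    return generate_corpus(SimulationConfig())


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(SimulationConfig(seed=13, n_genomes=30))
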