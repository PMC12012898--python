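import pytest

from triohap import simdata


@pytest.fixture(scope="session")
def small_config():
    """A fast trio fixture: 20 kb genomes at the default 4.6% divergence."""
    return simdata.SimConfig(genome_length=20_000, n_genes=20, coverage=20.0, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simdata.simulate_bundle(small_config)
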