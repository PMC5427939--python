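import numpy as np
import pytest

from rampfba import fixtures


@pytest.fixture(scope="session")
def toy():
    return fixtures.toy_example()


@pytest.fixture(scope="session")
def chain():
    return fixtures.chain_network()


@pytest.fixture(scope="session")
def parallel():
    return fixtures.parallel_paths_network()


@pytest.fixture(scope="session")
def random_nets():
    """A panel of seeded random networks shared across property tests."""
    return [fixtures.random_network(8, 14, seed) for seed in range(20)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
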