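import numpy as np
import pytest

from neurorc.connectome import make_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def random_connectome():
    """50-node directed weighted Erdos-Renyi graph."""
    return make_synthetic("random", 50, density=0.15, seed=1)


@pytest.fixture(scope="session")
def undirected_connectome():
    return make_synthetic("random", 40, density=0.2, directed=False, seed=2)


@pytest.fixture(scope="session")
def modular_connectome():
    return make_synthetic(
        "modular", 60, n_blocks=2, within_density=0.5, between_density=0.05, seed=3
    )
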