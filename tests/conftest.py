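import numpy as np
import pytest

from e3fam.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One 300-gene simulated study reused across read-only tests."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def desk_layout_dataset():
    """The 200-gene, 2-chromosome layout used by duplication tests."""
    return simulate_all(SimulationConfig(seed=1, n_genes=200))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
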