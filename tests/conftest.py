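import numpy as np
import pytest

from scfamap import SimulationConfig, load_registry, simulate_community


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def demo_truth(registry):
    """Mid-sized seeded community shared by tests that only read it."""
    config = SimulationConfig(seed=7, n_genomes=50, multi_pathway_rate=0.05)
    return simulate_community(config, registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
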