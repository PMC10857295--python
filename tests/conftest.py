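import numpy as np
import pytest

from nmcoupling.config import SimulationConfig, desk_preset
from nmcoupling.synthetic import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weighted_graph(rng, n, density=0.6, signed=True):
    """Random symmetric zero-diagonal weight matrix for oracle tests."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    if signed:
        w *= rng.choice([-1.0, 1.0], size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, k=1)
    return w + w.T


@pytest.fixture(scope="session")
def tiny_config():
    """A very small cohort configuration for fast structural tests."""
    return SimulationConfig(
        n_components=8, n_domains=3,
        group_sizes={"A": 8, "B": 6},
        n_timepoints=60, size_mean=10.0, size_sd=2.0,
        map_shape=(12, 12, 12), seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def desk_cohort():
    """Desk-preset null cohort (60/40/30 subjects, 20 components)."""
    return generate_cohort(desk_preset(seed=7, coupling_beta=0.0))
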