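import numpy as np
import pytest

from mosaicmap import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully-featured synthetic cohort shared across tests."""
    cfg = SimulationConfig(
        seed=0, n_controls=20, n_patients=8, V=300, N=30,
        atrophy_effect=6.0, atrophy_patch_fraction=0.15,
    )
    return simulate_cohort(cfg)
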