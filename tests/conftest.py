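import numpy as np
import pytest

from epiensemble.synthetic_data import (
    ExpressionConfig,
    SimulationConfig,
    simulate_families,
)


@pytest.fixture(scope="session")
def no_event_sim():
    """Four-species, ten-family simulation with no gene-family events."""
    return simulate_families(SimulationConfig(n_families=10, seed=7))


@pytest.fixture(scope="session")
def eventful_sim():
    """Simulation with duplications, losses and retrocopies."""
    cfg = SimulationConfig(
        n_families=20, dup_rate=0.4, loss_rate=0.2, retro_rate=0.6,
        unkn_fraction=0.3, seed=11,
    )
    return simulate_families(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
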