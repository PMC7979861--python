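import numpy as np
import pytest

from mesoclone.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort shared by IO/pipeline/integration tests."""
    cfg = SimulationConfig(
        n_patients=5, n_mutations_range=(30, 40), seed=11,
    )
    return simulate_cohort(cfg)
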