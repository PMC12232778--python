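import numpy as np
import pytest

from methdmr.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """One reduced synthetic cohort shared across read-only tests."""
    return simulate_dataset(SimulationConfig().small(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
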