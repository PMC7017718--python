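import numpy as np
import pytest

from dgcnet import simulate_scenario


@pytest.fixture(scope="session")
def constant_sim():
    """One constant-scenario realization shared across tests."""
    return simulate_scenario("constant", 1000, 12, seed=3)


@pytest.fixture(scope="session")
def shifting_sim():
    return simulate_scenario("shifting", 1000, 12, seed=7)


@pytest.fixture(scope="session")
def small_series():
    """Short 4-region constant-scenario series for cheap estimator tests."""
    ts, truth = simulate_scenario("constant", 600, 6, seed=11, block_size=3)
    return ts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
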