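import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phenorover import synthetic_field as synth

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_layout():
    """12-plot field (3 x 4) with six varieties, two replicates each."""
    return synth.gen_layout(3, 4, 15.0, ["A", "B", "C", "D", "E", "F"], seed=7)


@pytest.fixture(scope="session")
def small_truth(small_layout):
    return synth.default_truth(small_layout, seed=7)


@pytest.fixture(scope="session")
def noiseless_config():
    return synth.TrajectoryConfig(gps_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_trajectory(small_layout, noiseless_config):
    return synth.gen_trajectory(small_layout, noiseless_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
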