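import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myospec import SimulationConfig, simulate_irf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def irf_ch1(config):
    return simulate_irf(config, seed=0, channel=1)


@pytest.fixture(scope="session")
def irf_ch4(config):
    return simulate_irf(config, seed=0, channel=4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
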