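import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oculodyn.synthetic import generate_reference

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def henon5000():
    """Henon x-series, N=5000, literature D2 ~ 1.22, LLE ~ 0.42/iterate."""
    return generate_reference("henon", 5000, seed=1)


@pytest.fixture(scope="session")
def sine_series():
    """10 Hz sine at 1000 Hz: period 100 samples, quarter period 25."""
    return generate_reference("sine", 3000, {"frequency": 10.0}, seed=0)


@pytest.fixture(scope="session")
def white_noise_5000():
    return generate_reference("white_noise", 5000, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
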