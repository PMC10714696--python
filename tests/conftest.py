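import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_complete_panel(rng):
    """Small complete 3-occasion panel simulated from a known linear model."""
    n = 80
    times = (0.0, 1.0, 2.0)
    lam = np.column_stack([np.ones(3), times])
    eta = rng.multivariate_normal([10.0, 1.5], [[4.0, 0.5], [0.5, 1.0]], size=n)
    y = eta @ lam.T + rng.normal(0, 1.0, (n, 3))
    return times, y
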