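import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20170829)


def magnitude_noise(rng, signal, sigma, channels, size):
    """Sample root-sum-of-squares magnitudes: Rician (1ch) / 4-DOF chi (2ch)."""
    comps = rng.normal(0.0, sigma, size=(2 * channels,) + tuple(np.atleast_1d(size)))
    comps[0] += signal
    return np.sqrt((comps**2).sum(axis=0))


@pytest.fixture
def sample_magnitude_noise():
    return magnitude_noise
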