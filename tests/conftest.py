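import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.signal import lfilter

from gammakit.spectral import SpectralConfig
from gammakit.synthetic import calibrate_resonator, load_presets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_resonator_signal(
    f0: float, fwhm: float, fs: float, n: int, seed: int = 0, rms: float = 10.0
) -> np.ndarray:
    """Stationary AR-2 gamma oscillation with the requested RMS (test helper)."""
    from gammakit.synthetic import resonator_stationary_std

    b, a = calibrate_resonator(f0, fwhm, fs)
    rng = np.random.default_rng(seed)
    x = lfilter(b, a, rng.standard_normal(n))
    return x * (rms / resonator_stationary_std(a))


@pytest.fixture(scope="session")
def fast_cfg():
    """Spectral config for short test signals (30-s windows)."""
    return SpectralConfig(window_length=30.0, step=30.0)
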