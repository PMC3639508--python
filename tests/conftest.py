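import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vesiclekit.presets import make_preset
from vesiclekit.synthgen import _add_gaussian

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_fusion_preset():
    """Small, noise-free fusion preset for exact-value checks."""
    return make_preset(
        "fusion_noSyn",
        n_docked=20.0, n_fields=2,
        noise={"background": 0.0, "shot_noise": False, "read_sigma": 0.0},
    )


@pytest.fixture
def small_fusion_preset():
    """Small noisy fusion preset for fast pipeline runs."""
    return make_preset("fusion_noSyn", n_docked=25.0, n_fields=2)


def frame_with_spots(centers, flux=3000.0, sigma=1.3, size=128, background=100.0):
    """Noise-free frame with Gaussian spots at the given (x, y) centers."""
    frame = np.full((size, size), float(background))
    for x, y in centers:
        _add_gaussian(frame, x, y, flux, sigma)
    return frame
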