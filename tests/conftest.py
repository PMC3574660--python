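import numpy as np
import pytest

from meshreg import PhantomSpec, ScalarImage, WarpSpec, make_registration_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ramp_image():
    """Smooth 2-D ramp I(x, y) = x on a 16x16 grid."""
    x = np.arange(16, dtype=float)
    return ScalarImage(np.broadcast_to(x[:, None], (16, 16)).copy())


@pytest.fixture
def small_pair():
    """One deterministic synthetic registration problem (64x64)."""
    return make_registration_pair(
        PhantomSpec(shape=(64, 64), seed=7),
        WarpSpec(shape=(64, 64), amplitude_px=3.0, smoothness_sigma_px=8.0, seed=77),
    )
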