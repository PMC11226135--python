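import numpy as np
import pytest

from sactrack.synthetic import SacSimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """Small, fast synthetic world for unit tests (radii 20-50 px)."""
    return SacSimConfig(
        image_size=(192, 144),
        n_frames=8,
        r_lo=20.0,
        r_hi=50.0,
        center=(96.0, 60.0),
        seed=7,
    )


def circle_points(cx, cy, r, thetas):
    """Points exactly on a circle at the given angles (radians)."""
    thetas = np.asarray(thetas, dtype=float)
    return np.c_[cx + r * np.cos(thetas), cy + r * np.sin(thetas)]
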