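import numpy as np
import pytest

from ceustic import Cineloop, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless, motionless, texture-free homogeneous gland (fast)."""
    spec = PhantomSpec(
        shape=(64, 64), n_frames=120, frame_interval=0.5,
        lesion_type=None, noise_sigma=0.0, texture_sigma=0.0, seed=0,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def type1_phantom():
    """Noiseless Type-1 phantom at full acquisition size."""
    spec = PhantomSpec(lesion_type=1, noise_sigma=0.0, texture_sigma=0.0, seed=2)
    return make_phantom(spec)


@pytest.fixture()
def textured_loop():
    """Static random texture repeated over time — pure registration target."""
    rng = np.random.default_rng(11)
    base = rng.random((48, 48)) * 10.0 + 1.0
    frames = np.repeat(base[None], 8, axis=0)
    return Cineloop(frames=frames, times=np.arange(8.0))
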