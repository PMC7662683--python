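import numpy as np
import pytest

from copgait.dataset import ChannelSpec
from copgait.synthetic import GaitParams, ProtocolStep, simulate_session


@pytest.fixture(scope="session")
def walk_session():
    """60 s of steady walking at the 0.5 m/s reference speed, 3% noise."""
    return simulate_session(GaitParams(seed=1), [ProtocolStep(0.5, 0, 60.0, "walk")])


@pytest.fixture(scope="session")
def clean_walk_session():
    """Same kinematics as ``walk_session`` but noiseless."""
    return simulate_session(
        GaitParams(seed=1, noise_rel=0.0), [ProtocolStep(0.5, 0, 60.0, "walk")]
    )


@pytest.fixture(scope="session")
def mixed_session():
    """Short multi-step protocol: quiet standing, walking, perturbed walking."""
    proto = [
        ProtocolStep(0.0, 0, 20.0, "QS"),
        ProtocolStep(0.38, 0, 40.0, "walk_0.38"),
        ProtocolStep(0.5, 10, 40.0, "walk_0.50_p10"),
    ]
    return simulate_session(GaitParams(seed=2), proto)


@pytest.fixture
def gam_spec():
    return ChannelSpec()


def random_smooth_track(rng, n=300, dt=0.01, max_hz=2.0, amp=0.6):
    """Band-limited random Euler-angle track → unit-quaternion array."""
    from copgait import quaternion as qt

    t = np.arange(n) * dt
    angles = []
    for _ in range(3):
        sig = np.zeros(n)
        for _k in range(3):
            f = rng.uniform(0.1, max_hz)
            sig += rng.uniform(-amp, amp) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        angles.append(sig)
    return t, qt.sign_align(qt.from_euler_zyx(*angles))
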