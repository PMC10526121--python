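import numpy as np
import pytest

import circatwist as ct
from circatwist import perturbation


@pytest.fixture(scope="session")
def goodwin():
    return ct.make_default_spec("goodwin")


@pytest.fixture(scope="session")
def gonze():
    return ct.make_default_spec("gonze")


@pytest.fixture(scope="session")
def almeida():
    return ct.make_default_spec("almeida")


@pytest.fixture(scope="session")
def poincare():
    return ct.make_default_spec("poincare")


@pytest.fixture(scope="session")
def pulse_responses():
    """Pulsed/unpulsed twins at CT3 for the three canonical twist values."""
    out = {}
    for eps in (0.0, 0.1, -0.1):
        spec = ct.PoincareSpec(eps=eps)
        pulse = perturbation.pulse_at_ct(spec, 3.0)
        perturbed, reference = perturbation.pulse_response(spec, pulse)
        out[eps] = (spec, pulse, perturbed, reference)
    return out


def sine_trajectory(period=24.0, offset=2.0, t_end=240.0, dt=0.1, amp=1.0):
    t = np.arange(0.0, t_end + 1e-9, dt)
    x = offset + amp * np.cos(2.0 * np.pi * t / period)
    return ct.Trajectory(t, x[:, None], ("x",))
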