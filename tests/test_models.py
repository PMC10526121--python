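"""Model zoo: default parameter tables, right-hand sides, conversions."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import circatwist as ct
from circatwist import models


@pytest.mark.parametrize("model_id,expected", [
    ("goodwin", {"k1": 1.0, "k2": 0.2, "k3": 1.0, "k4": 0.15, "k5": 1.0,
                 "k6": 0.1, "K1": 1.0, "n": 9.5}),
    ("gonze", {"k1": 0.7, "k2": 0.35, "k3": 0.7, "k4": 0.35, "k5": 0.7,
               "k6": 0.35, "K1": 1.0, "K2": 1.0, "K4": 1.0, "K6": 1.0, "n": 4.0}),
    ("almeida", {"VR": 44.4, "kR": 3.54, "kRr": 80.1, "VE": 30.3, "kE": 214.0,
                 "kEr": 1.24, "VD": 202.0, "kD": 5.32, "kDr": 94.7,
                 "gamma_Ror": 2.55, "gamma_Rev": 0.241, "gamma_P": 0.844,
                 "gamma_C": 2.34, "gamma_DB": 0.156, "gamma_E4": 0.295,
                 "gamma_PC": 0.191, "gamma_CP": 0.141, "gamma_BP": 2.58}),
    ("poincare", {"A": 1.0, "lam": 0.05, "tau": 24.0, "eps": 0.0}),
    ("harmonic", {"m": 1.0, "k": 1.0}),
    ("duffing", {"m": 1.0, "k": 1.0, "beta": 1.0}),
])
def test_published_defaults(model_id, expected):
    spec = ct.make_default_spec(model_id)
    for name, value in expected.items():
        assert models.get_param(spec, name) == pytest.approx(value)


def test_unknown_model_names_valid_choices():
    with pytest.raises(ValueError, match="gonze"):
        ct.make_default_spec("kronauer")


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        ct.HarmonicSpec(m=-1.0)
    with pytest.raises(ValueError):
        ct.GoodwinSpec(n=0.5)
    with pytest.raises(ValueError):
        ct.PoincareSpec(lam=0.0)
    with pytest.raises(ValueError):
        models.ZeitgeberSpec(FZ=-0.1)
    with pytest.raises(KeyError):
        models.with_params(ct.GonzeSpec(), bogus=1.0)


def test_goodwin_rhs_at_origin(goodwin):
    # full repression relief at z = 0: production k1 only
    assert ct.eval_rhs(goodwin, [0.0, 0.0, 0.0]) == pytest.approx([1.0, 0.0, 0.0])


def test_gonze_rhs_hand_computed(gonze):
    # x production halved by z = 1 (K1 = 1, n = 4); z degraded at half Vmax
    d = ct.eval_rhs(gonze, [0.0, 0.0, 1.0])
    assert d == pytest.approx([0.35, 0.0, -0.175])


def test_poincare_polar_on_cycle_any_twist():
    for eps in (0.0, 0.1, -0.1, 1.0):
        spec = ct.PoincareSpec(eps=eps)
        dr, dphi = models.poincare_polar_rhs(spec, [spec.A, 0.7])
        assert dr == pytest.approx(0.0, abs=1e-15)
        assert dphi == pytest.approx(spec.omega)


def test_duffing_beta_zero_reduces_to_harmonic():
    harm = ct.HarmonicSpec(m=1.3, k=0.8)
    duff = ct.DuffingSpec(m=1.3, k=0.8, beta=0.0)
    # beta = 0 must be legal even though the default is nonzero
    rng = np.random.default_rng(0)
    for state in rng.normal(size=(20, 2)):
        assert ct.eval_rhs(duff, state) == pytest.approx(ct.eval_rhs(harm, state))


def test_poincare_cartesian_hand_computed():
    spec = ct.PoincareSpec(A=1.0, lam=0.05, tau=24.0, eps=0.1)
    omega = spec.omega
    # on-cycle point: pure rotation
    assert models.poincare_cartesian_rhs(spec, [1.0, 0.0]) == pytest.approx(
        [0.0, omega])
    # off-cycle point (2, 0): radial contraction and twisted rotation
    dx, dy = models.poincare_cartesian_rhs(spec, [2.0, 0.0])
    assert dx == pytest.approx(0.05 * 2.0 * (-1.0))
    assert dy == pytest.approx(2.0 * (omega - 0.1))
    # additive forcing enters x only
    dxf, dyf = models.poincare_cartesian_rhs(spec, [1.0, 0.0], Z=0.05)
    assert dxf == pytest.approx(0.05)
    assert dyf == pytest.approx(omega)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(r=st.floats(0.05, 3.0), phi=st.floats(-6.0, 6.0),
       eps=st.floats(-0.2, 0.2), lam=st.floats(0.01, 0.3))
def test_polar_and_cartesian_rhs_agree(r, phi, eps, lam):
    """The two coordinate charts describe one flow (oracle equivalence)."""
    spec = ct.PoincareSpec(A=1.0, lam=lam, tau=24.0, eps=eps)
    xy = models.polar_to_cartesian([r, phi])
    dxy = models.poincare_cartesian_rhs(spec, xy)
    dr, dphi = models.poincare_polar_rhs(spec, [r, phi])
    x, y = xy
    # chain rule: dx = dr*cos - r*sin*dphi, dy = dr*sin + r*cos*dphi
    assert dxy[0] == pytest.approx(dr * np.cos(phi) - r * np.sin(phi) * dphi,
                                   abs=1e-10)
    assert dxy[1] == pytest.approx(dr * np.sin(phi) + r * np.cos(phi) * dphi,
                                   abs=1e-10)


def test_eval_rhs_is_pure(gonze):
    state = np.array([0.3, 0.2, 0.9])
    before = state.copy()
    d1 = ct.eval_rhs(gonze, state)
    d2 = ct.eval_rhs(gonze, state)
    assert np.array_equal(state, before)
    assert np.array_equal(d1, d2)


def test_dimension_mismatch_and_illegal_forcing(goodwin, gonze):
    with pytest.raises(ValueError, match="dimension"):
        ct.eval_rhs(gonze, [1.0, 2.0])
    with pytest.raises(ValueError, match="poincare"):
        ct.eval_rhs(goodwin, [0.1, 0.1, 0.1], forcing=models.ZeitgeberSpec())


def test_pulse_value_inside_window_only():
    pulse = models.PulseSpec(FP=0.7, t_start=3.0, duration=1.0)
    assert models.pulse_value(pulse, 2.99) == 0.0
    assert models.pulse_value(pulse, 3.0) == 0.7
    assert models.pulse_value(pulse, 3.7) == 0.7
    assert models.pulse_value(pulse, 4.0) == 0.7
    assert models.pulse_value(pulse, 4.01) == 0.0


def test_zeitgeber_phase_offset():
    z = models.ZeitgeberSpec(FZ=0.05, T=24.0)
    assert models.zeitgeber_value(z, 0.0) == pytest.approx(0.0, abs=1e-15)
    # maximum a quarter period before each full period
    assert models.zeitgeber_value(z, 18.0) == pytest.approx(0.05)


def test_spec_serialization_round_trip():
    for model_id in models.MODEL_FAMILIES:
        spec = ct.make_default_spec(model_id)
        clone = models.spec_from_dict(models.spec_to_dict(spec))
        assert clone == spec
    tweaked = models.with_params(ct.GonzeSpec(), k4=0.21)
    assert models.spec_from_dict(models.spec_to_dict(tweaked)).k4 == 0.21


def test_omega_always_derived():
    spec = ct.PoincareSpec(tau=12.0)
    assert spec.omega == pytest.approx(np.pi / 6.0)
    assert "omega" not in [f.name for f in dataclasses.fields(spec)]
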