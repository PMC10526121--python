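"""Pulses, phase shifts, isochrones and phase space twist."""

import math

import numpy as np
import pytest

import circatwist as ct
from circatwist import models, perturbation as pert


def test_ct_convention():
    spec = ct.PoincareSpec()
    assert pert.ct_to_time(spec, 0.0) == 0.0
    assert pert.ct_to_time(spec, 6.0) == pytest.approx(6.0)   # quarter cycle
    assert pert.ct_to_time(spec, 27.0) == pytest.approx(3.0)  # wraps mod 24
    short = ct.PoincareSpec(tau=12.0)
    assert pert.ct_to_time(short, 6.0) == pytest.approx(3.0)


def test_ct3_plus_x_kick_raises_instantaneous_amplitude():
    spec = ct.PoincareSpec()
    phi = 2.0 * np.pi * 3.0 / 24.0
    state = np.array([np.cos(phi), np.sin(phi)])
    kicked = state + np.array([0.7, 0.0]) * 0.1   # short +x push
    assert np.hypot(*kicked) > np.hypot(*state)


def test_zero_strength_pulse_is_identity():
    spec = ct.PoincareSpec(eps=0.1)
    pulse = models.PulseSpec(FP=0.0, t_start=3.0)
    perturbed, reference = pert.pulse_response(spec, pulse,
                                               horizon=20 * 24.0)
    assert np.allclose(perturbed.X, reference.X, atol=1e-6)
    assert pert.phase_shift(perturbed, reference, spec) == pytest.approx(
        0.0, abs=1e-4)


def test_radial_kick_at_ct0_gives_no_shift_without_twist():
    """With eps = 0 the isochrones are radial: a +x kick at the x-maximum
    moves the state along its own isochrone.  The pulse window is centred
    on the maximum so its small tangential components cancel by symmetry
    (a window *starting* there rotates 15 degrees and picks up a net
    tangential push even without twist)."""
    spec = ct.PoincareSpec(eps=0.0)
    pulse = models.PulseSpec(FP=0.7, t_start=spec.tau - 0.5, duration=1.0)
    perturbed, reference = pert.pulse_response(spec, pulse)
    assert abs(pert.phase_shift(perturbed, reference, spec)) < 0.02


def test_relaxation_rate_after_pulse():
    spec = ct.PoincareSpec(eps=0.0, lam=0.05)
    pulse = pert.pulse_at_ct(spec, 3.0)
    perturbed, _ = pert.pulse_response(spec, pulse)
    w = perturbed.window(t_min=pulse.t_end + 1.0, t_max=pulse.t_end + 60.0)
    dev = np.abs(np.hypot(w.var("x"), w.var("y")) - spec.A)
    rate = -np.polyfit(w.t, np.log(dev), 1)[0]
    assert rate == pytest.approx(spec.lam * spec.A, rel=0.15)


def test_too_short_horizon_names_requirement():
    spec = ct.PoincareSpec()
    with pytest.raises(ValueError, match="h"):
        pert.pulse_response(spec, pert.pulse_at_ct(spec, 3.0), horizon=30.0)


def test_analytic_isochrone_closed_form():
    assert pert.analytic_isochrone(0.1, 0.05, 0.7, 1.0) == pytest.approx(0.7)
    assert pert.analytic_isochrone(0.0, 0.05, 0.7, 2.3) == pytest.approx(0.7)
    assert pert.analytic_isochrone(0.1, 0.05, 0.2, math.e) == pytest.approx(
        0.2 - 2.0)
    with pytest.raises(ValueError):
        pert.analytic_isochrone(0.1, 0.05, 0.0, -1.0)


def test_isochrone_curvature_scales_with_twist_to_relaxation_ratio():
    for eps, lam in [(0.1, 0.05), (-0.1, 0.05), (0.1, 0.025)]:
        field = pert.IsochroneField(eps=eps, lam=lam)
        dev = abs(float(field.latent_phase(0.0, 2.0)))
        assert dev == pytest.approx(abs(eps / lam) * math.log(2.0))


def test_strobe_on_cycle_returns_start_angle():
    spec = ct.PoincareSpec(eps=0.1)
    assert pert.strobe_latent_phase(spec, 0.9, 1.0) == pytest.approx(
        0.9, abs=1e-6)


def test_strobe_without_twist_keeps_angle_at_any_radius():
    spec = ct.PoincareSpec(eps=0.0)
    for r in (0.4, 1.7):
        assert pert.strobe_latent_phase(spec, 1.1, r) == pytest.approx(
            1.1, abs=1e-4)


def test_strobe_agrees_with_analytic_isochrone():
    spec = ct.PoincareSpec(eps=0.1, lam=0.05)
    got = pert.strobe_latent_phase(spec, 0.0, 1.3, tol=1e-6)
    want = float(pert.analytic_isochrone(0.1, 0.05, 0.0, 1.3))
    assert got == pytest.approx(want, abs=1e-3)


def test_strobe_rejects_nonpositive_radius():
    with pytest.raises(ValueError):
        pert.strobe_latent_phase(ct.PoincareSpec(), 0.0, 0.0)


def test_phase_shift_sign_follows_twist(pulse_responses):
    """An amplitude-increasing pulse delays a positive-twist clock
    (it relaxes through decelerated, r > A territory) and advances a
    negative-twist one."""
    shifts = {eps: pert.phase_shift(p, r, spec)
              for eps, (spec, pulse, p, r) in pulse_responses.items()}
    assert shifts[0.1] < -0.5
    assert shifts[-0.1] > 0.5
    assert shifts[0.1] < shifts[0.0] < shifts[-0.1]


def test_latent_phase_route_matches_crossing_route(pulse_responses):
    """Two independent readouts of the same shift: the strobed latent
    phase of the state at pulse end versus asymptotic crossing times."""
    for eps in (0.1, -0.1):
        spec, pulse, perturbed, reference = pulse_responses[eps]
        direct = pert.phase_shift(perturbed, reference, spec)
        via_isochrone = pert.latent_phase_shift(spec, perturbed, pulse)
        assert via_isochrone == pytest.approx(direct, abs=0.05)


def test_transient_twist_signature(pulse_responses):
    spec0, pulse0, p0, _ = pulse_responses[0.0]
    s0 = pert.transient_twist(p0, after=pulse0.t_end).table["peak_to_peak"]
    assert np.all(np.abs(s0 - 24.0) < 0.05)

    spec_p, pulse_p, pp, _ = pulse_responses[0.1]
    sp = pert.transient_twist(pp, after=pulse_p.t_end).table["peak_to_peak"]
    assert sp.iloc[0] > 24.0

    spec_n, pulse_n, pn, _ = pulse_responses[-0.1]
    sn = pert.transient_twist(pn, after=pulse_n.t_end).table["peak_to_peak"]
    assert sn.iloc[0] < 24.0


def test_transient_twist_amplitude_converges_to_cycle(pulse_responses):
    _, pulse, perturbed, _ = pulse_responses[0.1]
    table = pert.transient_twist(perturbed, after=pulse.t_end).table
    assert table["peak_to_trough"].iloc[-1] == pytest.approx(2.0, abs=0.01)
    assert table["peak_to_peak"].iloc[-1] == pytest.approx(24.0, abs=0.01)


def test_prc_zero_pulse_is_flat():
    spec = ct.PoincareSpec(eps=0.1)
    table = pert.prc(spec, FP=0.0, n_phases=8, horizon=12 * 24.0).table
    assert np.all(np.abs(table["phase_shift"]) < 1e-6)
    assert len(table) == 8


def test_prc_requires_enough_phases():
    with pytest.raises(ValueError):
        pert.prc(ct.PoincareSpec(), n_phases=4)
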