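"""Integration accuracy and period/amplitude/flag measurement."""

import numpy as np
import pytest

import circatwist as ct
from circatwist import models, rhythmometry as rh
from conftest import sine_trajectory


def test_harmonic_matches_cosine():
    traj = ct.integrate(ct.HarmonicSpec(), x0=(1.0, 0.0), t_end=100.0, dt_out=0.05)
    assert np.max(np.abs(traj.var("x") - np.cos(traj.t))) < 1e-6


def test_poincare_radius_relaxes_monotonically():
    spec = ct.PoincareSpec()
    traj = ct.integrate(spec, x0=(0.5, 0.0), t_end=200.0)
    r = np.hypot(traj.var("x"), traj.var("y"))
    assert np.all(np.diff(r) > -1e-9)
    assert r[-1] == pytest.approx(1.0, abs=1e-4)


def test_duffing_energy_conserved():
    spec = ct.DuffingSpec(beta=1.0)
    traj = ct.integrate(spec, x0=(1.0, 0.0), t_end=500.0, dt_out=0.05)
    E = spec.energy(traj.var("x"), traj.var("v"))
    assert np.max(np.abs(E - E[0])) / E[0] < 1e-6


@pytest.mark.parametrize("model_id", ["goodwin", "gonze", "almeida"])
def test_kinetic_trajectories_stay_nonnegative(model_id):
    spec = ct.make_default_spec(model_id)
    traj = ct.integrate(spec, t_end=300.0)
    assert traj.X.min() > -1e-8


def test_sinusoid_period_24():
    traj = sine_trajectory(period=24.0)
    assert rh.measure_period(traj, "x") == pytest.approx(24.0, abs=0.01)


def test_harmonic_closed_form_period():
    k = (2.0 * np.pi / 5.0) ** 2
    traj = ct.integrate(ct.HarmonicSpec(k=k), x0=(1.0, 0.0), t_end=100.0,
                        dt_out=0.01)
    assert rh.measure_period(traj, "x", discard=10.0, normalize=False) == \
        pytest.approx(5.0, abs=0.01)


def test_poincare_default_period_is_24h(poincare):
    traj = ct.integrate(poincare, t_end=700.0, t_record_from=100.0)
    assert rh.measure_period(traj, "x") == pytest.approx(24.0, abs=0.01)


def test_period_grid_refinement_consistent():
    coarse = rh.measure_period(sine_trajectory(dt=0.1), "x")
    fine = rh.measure_period(sine_trajectory(dt=0.05), "x")
    assert abs(coarse - fine) < 1e-3


def test_amplitude_mean_normalised():
    traj = sine_trajectory(offset=2.0)
    assert rh.measure_amplitude(traj, "x") == pytest.approx(1.0, abs=1e-3)


@pytest.mark.parametrize("eps", [0.0, 0.1, -0.1])
def test_poincare_cycle_amplitude_is_2A_for_any_twist(eps):
    """Twist acts off the cycle only; the cycle's peak-to-trough is always 2A."""
    spec = ct.PoincareSpec(eps=eps)
    traj = ct.integrate(spec, t_end=400.0, t_record_from=100.0)
    assert rh.measure_amplitude(traj, "x") == pytest.approx(2.0, abs=1e-3)


def test_damped_signal_classified_non_oscillatory():
    t = np.arange(0.0, 500.0, 0.1)
    x = np.exp(-t / 10.0) * np.cos(2.0 * np.pi * t / 24.0) + 2.0
    traj = ct.Trajectory(t, x[:, None], ("x",))
    m = rh.rhythm_metrics(traj, "x", discard=50.0)
    assert not m.oscillatory


def test_flat_signal_has_zero_amplitude():
    t = np.arange(0.0, 100.0, 0.1)
    traj = ct.Trajectory(t, np.full((t.size, 1), 3.0), ("x",))
    m = rh.rhythm_metrics(traj, "x")
    assert m.rel_amplitude == 0.0 and not m.oscillatory


def test_period_doubling_detection():
    t = np.arange(0.0, 480.0, 0.1)
    plain = 2.0 + np.cos(2.0 * np.pi * t / 24.0)
    # alternate peak heights 1.0 / 0.5 via a subharmonic component
    alternating = 2.0 + 0.75 * np.cos(2.0 * np.pi * t / 24.0) \
        + 0.25 * np.cos(2.0 * np.pi * t / 48.0)
    assert not rh.detect_period_doubling(ct.Trajectory(t, plain[:, None], ("x",)), "x")
    assert rh.detect_period_doubling(
        ct.Trajectory(t, alternating[:, None], ("x",)), "x")


def test_almeida_defaults_not_period_doubled(almeida):
    traj = ct.integrate(almeida, t_end=700.0, t_record_from=500.0)
    m = rh.rhythm_metrics(traj, "BMAL1")
    assert m.oscillatory and not m.period_doubling


@pytest.mark.parametrize("x0", [(0.3, 0.1), (1.8, -0.4)])
def test_limit_cycle_metrics_independent_of_start(poincare, x0):
    ref = ct.integrate(poincare, t_end=1100.0, t_record_from=960.0)
    other = ct.integrate(poincare, x0=x0, t_end=1100.0, t_record_from=960.0)
    assert rh.measure_period(other, "x") == pytest.approx(
        rh.measure_period(ref, "x"), abs=1e-3)
    assert rh.measure_amplitude(other, "x") == pytest.approx(
        rh.measure_amplitude(ref, "x"), abs=1e-3)


def test_batch_integration_matches_single(gonze):
    """The stacked batch path solves the same ODEs as the per-spec path."""
    single = ct.integrate(gonze, t_end=600.0, t_record_from=500.0)
    batched, = rh.integrate_batch([gonze], t_end=600.0, t_record_from=500.0)
    assert single.t.shape == batched.t.shape
    assert np.allclose(single.X, batched.X, atol=1e-4)
    assert rh.measure_period(batched, "x") == pytest.approx(
        rh.measure_period(single, "x"), abs=1e-5)


def test_trajectory_rejects_nan():
    with pytest.raises(ValueError):
        ct.Trajectory(np.array([0.0, 1.0]), np.array([[1.0], [np.nan]]), ("x",))


def test_integrate_validates_horizon(gonze):
    with pytest.raises(ValueError):
        ct.integrate(gonze, t_end=-1.0)


def test_non_oscillatory_returns_nan():
    t = np.arange(0.0, 100.0, 0.1)
    traj = ct.Trajectory(t, np.linspace(0.0, 1.0, t.size)[:, None], ("x",))
    assert np.isnan(rh.measure_period(traj, "x"))
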