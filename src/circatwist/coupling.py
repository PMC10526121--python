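"""Mean-field-coupled networks of twist oscillators.

Every member receives the mean field ``M(t) = (K/N) * sum_i x_i(t)``
additively in its ``x`` equation; the field is computed inside the joint
right-hand side (2N equations integrated together), never reconstructed
afterwards.  The field is held at zero before ``coupling_on_time`` so the
free-running and coupled epochs of one run can be compared, as in the
classic "switch the coupling on mid-run" protocol.

Twist shapes the coupled solution: coupling pumps the amplitude above A
by resonance, and with ``eps > 0`` the inflated radius slows the phase
velocity (longer network period) while ``eps < 0`` speeds it up.  In
mixed networks the members' relative phases to the mean field sort by
their twist: negative-twist members run ahead (phase advance),
positive-twist members lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import models, rhythmometry
from .models import CouplingSpec, PoincareSpec
from .rhythmometry import Trajectory

__all__ = [
    "NetworkDesign",
    "NetworkResult",
    "simulate_network",
    "coupled_period",
    "sync_order_parameter",
    "is_locked",
    "phase_offsets",
    "NotSynchronizedError",
]

LOCK_TOL = 0.05          # h: member/mean-field peak-spacing agreement


class NotSynchronizedError(RuntimeError):
    """The network is not synchronized; check sync_order_parameter diagnostics."""


@dataclass(frozen=True)
class NetworkDesign:
    """Mean-field network recipe.

    ``phase_spread='uniform'`` draws initial on-cycle phases uniformly
    (seeded); ``'zero'`` starts every member at phase 0 so all rhythms
    overlap until the coupling switches on.
    """

    specs: tuple[PoincareSpec, ...]
    coupling: CouplingSpec
    coupling_on_time: float = 240.0
    seed: int | None = None
    phase_spread: str = "uniform"

    def __post_init__(self):
        object.__setattr__(self, "specs", tuple(self.specs))
        if len(self.specs) != self.coupling.N:
            raise ValueError(
                f"coupling.N = {self.coupling.N} but {len(self.specs)} specs given"
            )
        if self.phase_spread not in ("uniform", "zero"):
            raise ValueError("phase_spread must be 'uniform' or 'zero'")


@dataclass
class NetworkResult:
    """Joint trajectories, the mean-field series and the design that made them."""

    traj: Trajectory              # columns x0, y0, x1, y1, ...
    mean_field: np.ndarray        # (K/N) * sum x_i; zero before coupling onset
    design: NetworkDesign

    @property
    def n(self) -> int:
        return len(self.design.specs)

    def member_xy(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self.traj.var(f"x{i}"), self.traj.var(f"y{i}")

    def to_frame(self) -> pd.DataFrame:
        frame = self.traj.to_frame()
        frame["mean_field"] = self.mean_field
        return frame


def simulate_network(design: NetworkDesign, horizon: float | None = None,
                     dt_out: float = rhythmometry.DT_OUT,
                     rtol: float = rhythmometry.RTOL,
                     atol: float = rhythmometry.ATOL) -> NetworkResult:
    """Integrate the 2N-dimensional coupled system.

    The horizon defaults to 40 of the slowest member's cycles after the
    coupling onset.  Members start on their limit cycles (radius A) at
    seeded or zero phases.
    """
    specs = design.specs
    n = len(specs)
    K = design.coupling.K
    t_on = design.coupling_on_time
    tau_max = max(s.tau for s in specs)
    if horizon is None:
        horizon = t_on + 40.0 * tau_max
    if horizon < t_on + 40.0 * tau_max - 1e-9:
        raise ValueError("horizon must cover >= 40 cycles after coupling onset")

    rng = np.random.default_rng(design.seed)
    if design.phase_spread == "uniform":
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
    else:
        phases = np.zeros(n)
    X0 = np.stack([np.array([s.A * math.cos(ph), s.A * math.sin(ph)])
                   for s, ph in zip(specs, phases)]).ravel()

    p = models.batch_params(specs)
    rhs = models.poincare_rhs

    def fun_free(t, y):
        return rhs(y.reshape(n, 2), p).ravel()

    def fun_coupled(t, y):
        Y = y.reshape(n, 2)
        M = K * Y[:, 0].mean()
        return rhs(Y, p, M=M).ravel()

    grid = np.arange(0.0, horizon + 0.5 * dt_out, dt_out)
    grid = grid[grid <= horizon + 1e-12]
    segments = [(0.0, min(t_on, horizon), fun_free)]
    if horizon > t_on:
        segments.append((t_on, horizon, fun_coupled))

    ts, Xs = [], []
    y = X0
    for lo, hi, fun in segments:
        t_eval = grid[(grid >= lo - 1e-12) & (grid < hi - 1e-12)]
        sol = solve_ivp(fun, (lo, hi), y, method="DOP853", rtol=rtol, atol=atol,
                        t_eval=np.append(t_eval, hi))
        if not sol.success:
            raise rhythmometry.IntegrationError(
                f"network integration failed: {sol.message}")
        y = sol.y[:, -1]
        if t_eval.size:
            ts.append(sol.t[:t_eval.size])
            Xs.append(sol.y.T[:t_eval.size])
    t_all = np.append(np.concatenate(ts), horizon)
    X_all = np.vstack(Xs + [y[None, :]])

    names = tuple(f"{v}{i}" for i in range(n) for v in ("x", "y"))
    traj = Trajectory(t_all, X_all, names)
    x_cols = X_all[:, 0::2]
    mean_field = np.where(t_all >= t_on, (K / n) * x_cols.sum(axis=1), 0.0)
    return NetworkResult(traj=traj, mean_field=mean_field, design=design)


def _coupled_signal(result: NetworkResult) -> np.ndarray:
    """Mean-field series, or the plain member average when K = 0."""
    if result.design.coupling.K > 0:
        return result.mean_field
    x_cols = result.traj.X[:, 0::2]
    return x_cols.mean(axis=1)


def is_locked(result: NetworkResult, n_cycles: int = 10,
              tol: float = LOCK_TOL) -> bool:
    """True when every member is frequency-locked to the mean field.

    Locking is judged by peak-spacing agreement (each member's mean
    x-peak spacing over the last ``n_cycles`` within ``tol`` hours of
    the mean field's), *not* by phase alignment: a locked network of
    mixed-twist clocks keeps finite phase lags, so the Kuramoto order
    parameter stays below 1 even in perfect lock.
    """
    try:
        offsets = phase_offsets(result, n_cycles=n_cycles)
    except NotSynchronizedError:
        return False
    return bool(np.all(np.isfinite(offsets)))


def coupled_period(result: NetworkResult, discard_cycles: float = 25.0) -> float:
    """Period (h) of the mean-field signal after the coupling onset.

    Raises :class:`NotSynchronizedError` for unsynchronized networks,
    where a mean-field period is not meaningful.
    """
    design = result.design
    if design.coupling.K > 0 and not is_locked(result):
        raise NotSynchronizedError(
            "network not frequency-locked; inspect sync_order_parameter, "
            "is_locked and per-member trajectories"
        )
    tau_max = max(s.tau for s in design.specs)
    t_min = design.coupling_on_time + discard_cycles * tau_max
    w = result.traj.window(t_min=t_min)
    signal = _coupled_signal(result)[result.traj.t >= t_min]
    zeros = rhythmometry.negative_slope_zeros(w.t, signal - signal.mean())
    if zeros.size < 2:
        raise NotSynchronizedError("mean field shows no oscillation")
    return float(np.diff(zeros).mean())


def sync_order_parameter(result: NetworkResult, window_cycles: float = 10.0) -> float:
    """Kuramoto order parameter of member phases, averaged over the last cycles.

    Phases are the ``atan2(y, x)`` angles; 1 means perfect phase
    alignment, values near 0 an incoherent network.
    """
    tau_max = max(s.tau for s in result.design.specs)
    t_min = result.traj.t[-1] - window_cycles * tau_max
    mask = result.traj.t >= t_min
    X = result.traj.X[mask]
    theta = np.arctan2(X[:, 1::2], X[:, 0::2])
    R = np.abs(np.exp(1j * theta).mean(axis=1))
    return float(R.mean())


def phase_offsets(result: NetworkResult, n_cycles: int = 10,
                  discard_cycles: float = 25.0) -> list[float]:
    """Per-member phase relative to the mean field, in hours; advance positive.

    The offset is the average over the last (up to) ``n_cycles`` of the
    mean-field x-peak time minus the member's nearest x-peak time,
    wrapped to half the coupled period on either side (so (-12, 12] for
    a 24-h network).  A member counts as phase-locked only if its mean
    peak spacing matches the mean field's within ``LOCK_TOL`` *and* its
    spacing variability stays below the same tolerance; otherwise its
    offset is NaN.
    """
    design = result.design
    tau_max = max(s.tau for s in design.specs)
    t_min = design.coupling_on_time + discard_cycles * tau_max
    w = result.traj.window(t_min=t_min)
    mf = _coupled_signal(result)[result.traj.t >= t_min]
    mf_peaks, _ = rhythmometry.find_peaks(w.t, mf)
    if mf_peaks.size < 4:
        raise NotSynchronizedError("mean field shows too few peaks")
    k = min(n_cycles, mf_peaks.size - 1)
    mf_peaks = mf_peaks[-(k + 1):]
    mf_spacing = float(np.diff(mf_peaks).mean())
    half = mf_spacing / 2.0

    offsets = []
    for i in range(result.n):
        x = w.var(f"x{i}")
        pk, _ = rhythmometry.find_peaks(w.t, x)
        if pk.size < k + 1:
            offsets.append(math.nan)
            continue
        spacings = np.diff(pk[-(k + 1):])
        if abs(spacings.mean() - mf_spacing) > LOCK_TOL \
                or spacings.std() > LOCK_TOL:
            offsets.append(math.nan)
            continue
        deltas = []
        for tp in mf_peaks:
            nearest = pk[np.argmin(np.abs(pk - tp))]
            delta = (tp - nearest + half) % mf_spacing - half
            deltas.append(half if delta == -half else delta)
        offsets.append(float(np.mean(deltas)))
    return offsets
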