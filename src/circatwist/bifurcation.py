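"""Steady states, linear stability and Hopf-bubble scans.

A one-parameter scan tracks the steady state by continuation (the
previous grid point's solution seeds the next root solve), records the
largest real part of the Jacobian eigenvalues, refines every sign change
by bisection, and — inside the oscillatory interval (the *Hopf bubble*)
— measures the simulated extrema and period of the tracked variable.
This replaces pseudo-arclength continuation: the bubbles handled here
are plain one-parameter Hopf pairs.

For the Goodwin and Gonze loops the steady state reduces to a scalar
fixed-point equation in the repressor ``z``, which is solved by bracketed
bisection and is therefore immune to the sign problems a blind
multidimensional Newton run can have with fractional Hill exponents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import models, rhythmometry
from .models import model_id_of, with_params

__all__ = [
    "BifurcationBranch",
    "SteadyStateError",
    "find_steady_state",
    "numerical_jacobian",
    "jacobian_eigenvalues",
    "hopf_scan",
    "twist_from_branch",
]

RESIDUAL_TOL = 1e-10
PARAM_TOL = 1e-3


class SteadyStateError(RuntimeError):
    """Steady-state solve failed; try a different initial guess."""


@dataclass
class BifurcationBranch:
    """One-parameter branch: steady-state stability plus simulated extrema."""

    param_name: str
    param_values: np.ndarray
    steady_states: np.ndarray          # (n_grid, dim)
    leading_eig_real: np.ndarray       # max Re(eigenvalue) per grid point
    osc_max: np.ndarray                # post-transient max of mean-normalised var
    osc_min: np.ndarray
    period: np.ndarray                 # h; NaN outside the bubble
    hopf_points: tuple[float, ...]
    var: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.param_name: self.param_values,
            "leading_eig_real": self.leading_eig_real,
            "osc_max": self.osc_max,
            "osc_min": self.osc_min,
            "period": self.period,
        })


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

def _goodwin_like_steady_state(spec) -> np.ndarray:
    """Unique positive fixed point of the Goodwin/Gonze loop via scalar bisection."""
    mid = model_id_of(spec)
    p = {name: getattr(spec, name) for name in models.param_names(spec)}

    if mid == "goodwin":
        def x_of(q):          # q = transcription flux at the fixed point
            return q / p["k2"]

        def y_of(x):
            return p["k3"] * x / p["k4"]

        def z_of(y):
            return p["k5"] * y / p["k6"]
    else:  # gonze: invert the Michaelis-Menten degradation terms
        def _invert_mm(q, vmax, K):
            if q >= vmax:     # production exceeds maximal degradation
                raise SteadyStateError(
                    "no finite steady state: production flux exceeds the "
                    "maximal Michaelis-Menten degradation rate"
                )
            return K * q / (vmax - q)

        def x_of(q):
            return _invert_mm(q, p["k2"], p["K2"])

        def y_of(x):
            return _invert_mm(p["k3"] * x, p["k4"], p["K4"])

        def z_of(y):
            return _invert_mm(p["k5"] * y, p["k6"], p["K6"])

    def hill(z):
        return p["k1"] * p["K1"] ** p["n"] / (p["K1"] ** p["n"] + z ** p["n"])

    def residual(z):
        return z_of(y_of(x_of(hill(z)))) - z

    if mid == "goodwin":
        z_hi = z_of(y_of(x_of(hill(0.0))))   # repression-free upper bound
        z_lo = 1e-12
    else:
        # Michaelis-Menten ceilings make the chain infeasible at weak
        # repression (small z); bracket the root from the feasible side,
        # where residual -> +inf at the feasibility boundary and -> -z
        # as z -> inf.
        z_hi = max(p["K1"], 1.0)
        for _ in range(200):
            try:
                if residual(z_hi) < 0:
                    break
            except SteadyStateError:
                pass
            z_hi *= 2.0
        else:
            raise SteadyStateError("no finite steady state found (no upper bracket)")
        z_lo, infeasible = z_hi / 2.0, None
        for _ in range(200):
            try:
                if residual(z_lo) > 0:
                    break
                z_hi = z_lo            # still negative: tighten from above
            except SteadyStateError:
                infeasible = z_lo      # crossed the feasibility boundary
            if infeasible is None:
                z_lo /= 2.0
                if z_lo < 1e-14:
                    raise SteadyStateError(
                        "no positive steady state: residual never positive")
            else:
                z_lo = 0.5 * (infeasible + z_hi)   # bisect toward the boundary
        else:
            raise SteadyStateError("steady-state bracketing failed")
    z_star = optimize.brentq(residual, z_lo, z_hi, xtol=1e-14, rtol=1e-15)
    x_star = x_of(hill(z_star))
    return np.array([x_star, y_of(x_star), z_star])


def find_steady_state(spec, guess=None, tol: float = RESIDUAL_TOL) -> np.ndarray:
    """Fixed point of the model's flow, with residual norm below ``tol``.

    Goodwin/Gonze use a bracketed scalar reduction (always the unique
    positive fixed point); other families run a Newton-type solve from
    ``guess`` (model default when omitted).  Harmonic/Duffing and the
    Poincare model have the origin as their only fixed point.
    """
    mid = model_id_of(spec)
    if guess is None:
        if mid in ("goodwin", "gonze"):
            state = _goodwin_like_steady_state(spec)
            res = np.linalg.norm(models.eval_rhs(spec, state))
            if res > tol:
                raise SteadyStateError(f"steady-state residual {res:.2e} > {tol:g}")
            return state
        if mid in ("harmonic", "duffing", "poincare"):
            return np.zeros(len(models.var_names(spec)))
        guess = models.default_initial_state(spec)

    sol = optimize.root(lambda y: models.eval_rhs(spec, y), np.asarray(guess, float),
                        method="hybr", tol=1e-13)
    state = sol.x
    res = np.linalg.norm(models.eval_rhs(spec, state))
    if not sol.success or res > tol:
        raise SteadyStateError(
            f"steady-state solve failed for {mid!r} (residual {res:.2e}); "
            "try a different guess"
        )
    return state


def numerical_jacobian(fun: Callable[[np.ndarray], np.ndarray], state: np.ndarray,
                       rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of ``fun`` at ``state``."""
    state = np.asarray(state, dtype=float)
    dim = state.size
    J = np.empty((dim, dim))
    for j in range(dim):
        h = rel_step * max(abs(state[j]), 1.0)
        up = state.copy()
        dn = state.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (np.asarray(fun(up)) - np.asarray(fun(dn))) / (2.0 * h)
    return J


def jacobian_eigenvalues(spec, state) -> np.ndarray:
    """Eigenvalues of the numerically differenced Jacobian at ``state``."""
    J = numerical_jacobian(lambda y: models.eval_rhs(spec, y), np.asarray(state, float))
    return np.linalg.eigvals(J)


def _leading_real(spec, guess=None) -> tuple[float, np.ndarray]:
    ss = find_steady_state(spec, guess=guess)
    eig = jacobian_eigenvalues(spec, ss)
    return float(eig.real.max()), ss


# ---------------------------------------------------------------------------
# Hopf scan
# ---------------------------------------------------------------------------

def hopf_scan(spec, param_name: str, lo: float, hi: float, n_grid: int = 100,
              var: str | None = None, simulate: bool = True,
              discard: float = rhythmometry.BIOCHEM_DISCARD,
              measure_window: float = 200.0,
              param_tol: float = PARAM_TOL) -> BifurcationBranch:
    """Scan a parameter, locate Hopf points and trace the bubble.

    The steady state is continued across a uniform grid; each sign change
    of the leading eigenvalue real part is refined by bisection to
    ``param_tol``.  With ``simulate`` on, grid points with an unstable
    steady state are integrated (as one batch) and the post-transient
    extrema of the mean-normalised tracked variable and its period are
    recorded.  If steady-state tracking fails midway the partial branch
    is returned with the remaining grid marked NaN.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if var is None:
        var = models.var_names(spec)[0]
    grid = np.linspace(lo, hi, n_grid)
    leading = np.full(n_grid, math.nan)
    states = np.full((n_grid, len(models.var_names(spec))), math.nan)

    guess = None
    for i, value in enumerate(grid):
        s_i = with_params(spec, **{param_name: float(value)})
        try:
            leading[i], states[i] = _leading_real(s_i, guess=guess)
            guess = None if model_id_of(spec) in ("goodwin", "gonze") else states[i]
        except SteadyStateError:
            import warnings

            warnings.warn(
                f"steady-state tracking lost at {param_name}={value:g}; "
                "returning a partial branch"
            )
            break

    hopf: list[float] = []
    for i in range(n_grid - 1):
        a, b = leading[i], leading[i + 1]
        if np.isfinite(a) and np.isfinite(b) and a * b < 0:
            def f(value, _guess=states[i]):
                s_v = with_params(spec, **{param_name: float(value)})
                return _leading_real(s_v, guess=None
                                     if model_id_of(spec) in ("goodwin", "gonze")
                                     else _guess)[0]

            hopf.append(float(optimize.brentq(f, grid[i], grid[i + 1],
                                              xtol=param_tol)))

    osc_max = np.full(n_grid, math.nan)
    osc_min = np.full(n_grid, math.nan)
    period = np.full(n_grid, math.nan)
    if simulate:
        unstable = np.where(leading > 0)[0]
        if unstable.size:
            # track the limit cycle by continuation: settle once at the most
            # unstable grid point, then walk outward restarting each member
            # from its neighbour's final state.  This sidesteps the critical
            # slowing down near the Hopf points, where settling from a cold
            # start would take thousands of hours.
            center = int(unstable[np.argmax(leading[unstable])])
            left = [i for i in unstable[unstable < center][::-1]]
            right = [i for i in unstable[unstable > center]]

            def _measure(i, x0, settle):
                s_i = with_params(spec, **{param_name: float(grid[i])})
                traj = rhythmometry.integrate(
                    s_i, x0=x0, t_end=settle + measure_window,
                    t_record_from=settle)
                y = traj.var(var)
                s = y / y.mean()
                osc_max[i] = s.max()
                osc_min[i] = s.min()
                period[i] = rhythmometry.measure_period(traj, var)
                return traj.X[-1]

            state = _measure(center, None, discard)
            for side in (left, right):
                x_prev = state
                for i in side:
                    x_prev = _measure(i, x_prev, measure_window * 3.0)

    return BifurcationBranch(
        param_name=param_name, param_values=grid, steady_states=states,
        leading_eig_real=leading, osc_max=osc_max, osc_min=osc_min,
        period=period, hopf_points=tuple(hopf), var=var,
    )


def twist_from_branch(branch: BifurcationBranch) -> pd.DataFrame:
    """(period, amplitude) curve along the bubble, parameter order preserved.

    Amplitude is ``osc_max - osc_min`` of the mean-normalised tracked
    variable.  Because the parameter ordering is kept, a non-monotonic
    amplitude-period relation (amplitude rising then falling across the
    bubble while the period moves monotonically) remains visible.
    """
    mask = np.isfinite(branch.period)
    if mask.sum() < 3:
        raise ValueError("branch has fewer than 3 oscillatory grid points")
    return pd.DataFrame({
        branch.param_name: branch.param_values[mask],
        "period": branch.period[mask],
        "amplitude": (branch.osc_max - branch.osc_min)[mask],
    })
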