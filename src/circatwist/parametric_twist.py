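"""Parametric twist: amplitude-period correlations in heterogeneous ensembles.

An ensemble of uncoupled oscillators is built by multiplying selected
parameters of a base model by independent uniform factors on
``[1 - frac, 1 + frac]`` — e.g. ``frac = 0.1`` for the +/-10% degradation-rate
heterogeneity used with the Goodwin/Gonze loop models and ``frac = 0.2``
for the +/-20% single-parameter heterogeneity of the Almeida clock model.
Each member is integrated, its period and relative amplitude are measured,
non-oscillatory and period-doubled members are filtered out, and the
surviving (period, amplitude) pairs are rank-correlated (Spearman).

A significant positive correlation marks a *soft* (positive-twist)
ensemble, a significant negative one a *hard* (negative-twist) ensemble.
In amplitude-ratio mode (amplitudes divided by the unperturbed default
amplitude) an ensemble whose ratio range stays below 0.1 is classified as
having *no twist* regardless of the rank statistic.

Conservative oscillators (harmonic/Duffing) have no limit cycle, so their
twist is probed by sweeping initial displacements instead of parameters;
see :func:`initial_condition_twist`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import models, rhythmometry
from .models import model_id_of, param_names, with_params
from .rhythmometry import BIOCHEM_DISCARD, RhythmMetrics, Trajectory

#: per-family transient discard (h): the Gonze cycle attracts slowly
#: (Floquet timescale ~800 h), so it needs a longer settling window
FAMILY_DISCARD = {"gonze": 1000.0}

__all__ = [
    "EnsembleDesign",
    "TwistTable",
    "draw_ensemble",
    "ensemble_metrics",
    "apply_filters",
    "twist_correlation",
    "ensemble_twist",
    "initial_condition_twist",
    "NoOscillatorsRetained",
]

#: Fig-3-style relative-amplitude floor below which members are discarded
MIN_REL_AMPLITUDE = 0.1

#: significance level for calling a twist sign
TWIST_ALPHA = 1e-3

#: amplitude-ratio range below which an ensemble has "no twist" (ratio mode)
NO_TWIST_RATIO_RANGE = 0.1


class NoOscillatorsRetained(RuntimeError):
    """All ensemble members were filtered out."""


@dataclass(frozen=True)
class EnsembleDesign:
    """Recipe for a heterogeneous uncoupled ensemble.

    ``varied_params`` are drawn independently of each other (joint
    heterogeneity multiplies each listed parameter by its own factor).
    """

    base: object
    varied_params: tuple[str, ...]
    frac: float = 0.1
    n: int = 100
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "varied_params", tuple(self.varied_params))
        if not (0.0 <= self.frac < 1.0):
            raise ValueError("heterogeneity fraction must satisfy 0 <= frac < 1")
        if self.n < 2:
            raise ValueError("ensemble size n must be >= 2")
        if not self.varied_params:
            raise ValueError("varied_params must be non-empty")
        known = set(param_names(self.base))
        unknown = set(self.varied_params) - known
        if unknown:
            raise ValueError(
                f"parameters {sorted(unknown)} not in {type(self.base).__name__}"
            )


@dataclass
class TwistTable:
    """Per-member rhythm table plus the ensemble-level rank statistics."""

    rows: pd.DataFrame
    spearman_rho: float
    p_value: float
    label: str                    # 'positive' | 'negative' | 'none'
    n_retained: int

    def summary(self) -> dict:
        return {
            "spearman_rho": self.spearman_rho,
            "p_value": self.p_value,
            "label": self.label,
            "n_retained": self.n_retained,
        }


def draw_ensemble(design: EnsembleDesign) -> list:
    """Draw the ensemble member specs (reproducible given ``design.seed``)."""
    rng = np.random.default_rng(design.seed)
    members = []
    for _ in range(design.n):
        factors = rng.uniform(1.0 - design.frac, 1.0 + design.frac,
                              size=len(design.varied_params))
        overrides = {
            name: models.get_param(design.base, name) * f
            for name, f in zip(design.varied_params, factors)
        }
        members.append(with_params(design.base, **overrides))
    return members


def _integrate_ensemble(specs: Sequence, discard: float | None = None,
                        t_end: float | None = None,
                        dt_out: float = rhythmometry.DT_OUT,
                        batch: bool = True) -> list:
    """Integrate every member (batched when possible); None for failed members."""
    mid = model_id_of(specs[0])
    if discard is None:
        discard = FAMILY_DISCARD.get(mid, BIOCHEM_DISCARD)
    if t_end is None:
        t_end = discard + 200.0
    if batch:
        try:
            return rhythmometry.integrate_batch(
                specs, t_end=t_end, dt_out=dt_out, t_record_from=discard)
        except rhythmometry.IntegrationError:
            pass
    trajs = []
    for s in specs:
        try:
            trajs.append(rhythmometry.integrate(
                s, t_end=t_end, dt_out=dt_out, t_record_from=discard))
        except rhythmometry.IntegrationError:
            trajs.append(None)
    return trajs


def ensemble_metrics(specs: Sequence, var: str | None = None,
                     discard: float | None = None, t_end: float | None = None,
                     dt_out: float = rhythmometry.DT_OUT,
                     varied_params: Sequence[str] | None = None,
                     batch: bool = True) -> pd.DataFrame:
    """Integrate every member and tabulate period/amplitude/flags.

    Members that fail to oscillate are kept in the table with
    ``oscillatory = False`` (filters decide their fate); a member whose
    integration fails outright is recorded with NaN metrics rather than
    aborting the ensemble.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("empty ensemble")
    if var is None:
        var = models.var_names(specs[0])[0]
    trajs = _integrate_ensemble(specs, discard=discard, t_end=t_end,
                                dt_out=dt_out, batch=batch)
    if varied_params is None:
        varied_params = param_names(specs[0])
    records = []
    for i, (s, traj) in enumerate(zip(specs, trajs)):
        rec = {"member": i}
        rec.update({name: models.get_param(s, name) for name in varied_params})
        if traj is None:
            rec.update(period=math.nan, rel_amplitude=math.nan,
                       oscillatory=False, period_doubling=False)
        else:
            m = rhythmometry.rhythm_metrics(traj, var)
            rec.update(period=m.period, rel_amplitude=m.rel_amplitude,
                       oscillatory=m.oscillatory,
                       period_doubling=m.period_doubling)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def apply_filters(rows: pd.DataFrame, min_rel_amplitude: float = MIN_REL_AMPLITUDE,
                  drop_period_doubling: bool = True) -> pd.DataFrame:
    """Drop non-oscillatory, low-amplitude and (optionally) period-doubled rows."""
    keep = rows["oscillatory"] & (rows["rel_amplitude"] >= min_rel_amplitude) \
        & rows["period"].notna()
    if drop_period_doubling:
        keep &= ~rows["period_doubling"]
    out = rows[keep].copy()
    if out.empty:
        raise NoOscillatorsRetained(
            "no oscillators retained after amplitude/period-doubling filters"
        )
    return out


def _spearman(period: np.ndarray, amplitude: np.ndarray,
              seed: int = 0) -> tuple[float, float]:
    """Two-sided Spearman rho and p; permutation-based below n = 20."""
    n = period.size
    if np.unique(period).size < 2 or np.unique(amplitude).size < 2:
        return math.nan, math.nan
    rho, p = stats.spearmanr(period, amplitude)
    if n < 20:
        res = stats.permutation_test(
            (period,), lambda x: stats.spearmanr(x, amplitude).statistic,
            permutation_type="pairings", alternative="two-sided",
            n_resamples=9999, rng=np.random.default_rng(seed),
        )
        p = res.pvalue
    return float(rho), float(p)


def twist_correlation(rows: pd.DataFrame, amplitude_mode: str = "relative",
                      default_amplitude: float | None = None,
                      alpha: float = TWIST_ALPHA) -> TwistTable:
    """Spearman rank correlation of amplitude against period.

    Parameters
    ----------
    amplitude_mode : {'relative', 'ratio-to-default'}
        ``'relative'`` correlates the relative amplitudes directly;
        ``'ratio-to-default'`` first divides them by ``default_amplitude``
        (the unperturbed base model's amplitude) and declares *no twist*
        when the resulting ratio range is below 0.1.
    alpha
        Significance level for labelling the sign (default 1e-3).
    """
    if amplitude_mode not in ("relative", "ratio-to-default"):
        raise ValueError("amplitude_mode must be 'relative' or 'ratio-to-default'")
    rows = rows.copy()
    if amplitude_mode == "ratio-to-default":
        if default_amplitude is None or default_amplitude <= 0:
            raise ValueError("ratio-to-default mode needs the default amplitude")
        rows["amplitude"] = rows["rel_amplitude"] / default_amplitude
    else:
        rows["amplitude"] = rows["rel_amplitude"]
    if len(rows) < 3:
        raise ValueError("need at least 3 retained rows for a rank correlation")

    period = rows["period"].to_numpy(float)
    amplitude = rows["amplitude"].to_numpy(float)
    rho, p = _spearman(period, amplitude)

    label = "none"
    if np.isfinite(rho) and np.isfinite(p) and p < alpha:
        label = "positive" if rho > 0 else "negative"
    if amplitude_mode == "ratio-to-default":
        if amplitude.max() - amplitude.min() < NO_TWIST_RATIO_RANGE:
            label = "none"
    return TwistTable(rows=rows, spearman_rho=rho, p_value=p,
                      label=label, n_retained=len(rows))


def ensemble_twist(design: EnsembleDesign, var: str | None = None,
                   amplitude_mode: str = "relative",
                   discard: float | None = None, t_end: float | None = None,
                   min_rel_amplitude: float = MIN_REL_AMPLITUDE,
                   drop_period_doubling: bool = True) -> TwistTable:
    """Full pipeline: draw -> integrate -> measure -> filter -> correlate."""
    specs = draw_ensemble(design)
    rows = ensemble_metrics(specs, var=var, discard=discard, t_end=t_end,
                            varied_params=design.varied_params)
    rows = apply_filters(rows, min_rel_amplitude=min_rel_amplitude,
                         drop_period_doubling=drop_period_doubling)
    default_amplitude = None
    if amplitude_mode == "ratio-to-default":
        base_rows = ensemble_metrics([design.base], var=var, discard=discard,
                                     t_end=t_end, varied_params=())
        default_amplitude = float(base_rows["rel_amplitude"].iloc[0])
    return twist_correlation(rows, amplitude_mode=amplitude_mode,
                             default_amplitude=default_amplitude)


def ensemble_twist_by_variable(design: EnsembleDesign, variables: Sequence[str],
                               amplitude_mode: str = "relative",
                               discard: float | None = None,
                               t_end: float | None = None,
                               min_rel_amplitude: float = MIN_REL_AMPLITUDE,
                               drop_period_doubling: bool = True,
                               ) -> dict[str, TwistTable]:
    """Twist tables for several measured variables from one ensemble run.

    Integrates the ensemble (and, in ratio mode, the unperturbed base
    model) once and reads every requested variable off the same
    trajectories — the natural protocol for multi-variable clock models,
    where the twist sign can differ between proteins of the same network.
    """
    specs = draw_ensemble(design)
    trajs = _integrate_ensemble(specs, discard=discard, t_end=t_end)
    base_trajs = None
    if amplitude_mode == "ratio-to-default":
        base_trajs = _integrate_ensemble([design.base], discard=discard,
                                         t_end=t_end)
    out = {}
    for var in variables:
        records = []
        for i, (s, traj) in enumerate(zip(specs, trajs)):
            rec = {"member": i}
            rec.update({name: models.get_param(s, name)
                        for name in design.varied_params})
            if traj is None:
                rec.update(period=math.nan, rel_amplitude=math.nan,
                           oscillatory=False, period_doubling=False)
            else:
                m = rhythmometry.rhythm_metrics(traj, var)
                rec.update(period=m.period, rel_amplitude=m.rel_amplitude,
                           oscillatory=m.oscillatory,
                           period_doubling=m.period_doubling)
            records.append(rec)
        rows = apply_filters(pd.DataFrame.from_records(records),
                             min_rel_amplitude=min_rel_amplitude,
                             drop_period_doubling=drop_period_doubling)
        default_amplitude = None
        if base_trajs is not None:
            default_amplitude = rhythmometry.rhythm_metrics(
                base_trajs[0], var).rel_amplitude
        out[var] = twist_correlation(rows, amplitude_mode=amplitude_mode,
                                     default_amplitude=default_amplitude)
    return out


def initial_condition_twist(spec, displacements: Sequence[float],
                            t_end: float = 200.0, discard: float = 50.0,
                            dt_out: float = 0.01) -> TwistTable:
    """Amplitude-period sweep over initial displacements (conservative models).

    Each member starts at rest, ``(x0, 0)``; period and raw peak-to-trough
    amplitude of ``x`` are measured after the discard window.  For the
    harmonic oscillator the rank correlation is undefined (all periods
    equal); for Duffing springs the sign of the correlation is the sign
    of the twist (soft ``beta < 0``: positive, hard ``beta > 0``: negative).
    """
    records = []
    for i, x0 in enumerate(displacements):
        traj = rhythmometry.integrate(spec, x0=(float(x0), 0.0), t_end=t_end,
                                      dt_out=dt_out, t_record_from=discard)
        period = rhythmometry.measure_period(traj, "x", normalize=False)
        amp = rhythmometry.measure_amplitude(traj, "x", normalize=False)
        records.append({"member": i, "x0": float(x0), "period": period,
                        "rel_amplitude": amp, "oscillatory": np.isfinite(period),
                        "period_doubling": False})
    rows = pd.DataFrame.from_records(records)
    rows = rows[rows["oscillatory"]]
    return twist_correlation(rows, amplitude_mode="relative")
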