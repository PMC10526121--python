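"""Ensemble construction, filtering and the twist rank statistic."""

import math

import numpy as np
import pandas as pd
import pytest

import circatwist as ct
from circatwist import models, parametric_twist as pt


def _rows(period, amplitude):
    n = len(period)
    return pd.DataFrame({
        "member": range(n), "period": period, "rel_amplitude": amplitude,
        "oscillatory": [True] * n, "period_doubling": [False] * n,
    })


def test_frac_zero_gives_identical_members(gonze):
    design = pt.EnsembleDesign(base=gonze, varied_params=("k4",), frac=0.0,
                               n=5, seed=0)
    assert all(s == gonze for s in pt.draw_ensemble(design))


def test_draw_bounds_and_reproducibility(gonze):
    design = pt.EnsembleDesign(base=gonze, varied_params=("k4",), frac=0.1,
                               n=200, seed=7)
    k4 = np.array([s.k4 for s in pt.draw_ensemble(design)])
    assert np.all(k4 >= 0.9 * gonze.k4) and np.all(k4 <= 1.1 * gonze.k4)
    k4_again = np.array([s.k4 for s in pt.draw_ensemble(design)])
    assert np.array_equal(k4, k4_again)


def test_draw_sample_mean_near_default(gonze):
    # law of large numbers: the uniform factor is centred on 1
    design = pt.EnsembleDesign(base=gonze, varied_params=("k4",), frac=0.1,
                               n=10000, seed=3)
    k4 = np.array([s.k4 for s in pt.draw_ensemble(design)])
    assert abs(k4.mean() / gonze.k4 - 1.0) < 0.005


def test_design_validation(gonze):
    with pytest.raises(ValueError):
        pt.EnsembleDesign(base=gonze, varied_params=(), frac=0.1, n=10)
    with pytest.raises(ValueError):
        pt.EnsembleDesign(base=gonze, varied_params=("k4",), frac=1.2, n=10)
    with pytest.raises(ValueError):
        pt.EnsembleDesign(base=gonze, varied_params=("k4",), frac=0.1, n=1)
    with pytest.raises(ValueError):
        pt.EnsembleDesign(base=gonze, varied_params=("k99",), frac=0.1, n=10)


def test_identical_poincare_ensemble_periods_agree():
    spec = ct.PoincareSpec()
    rows = pt.ensemble_metrics([spec] * 4, var="x", discard=200.0, t_end=400.0)
    assert np.allclose(rows["period"], 24.0, atol=1e-3)


def test_monotone_pairs_give_extreme_rho():
    period = np.linspace(22.0, 26.0, 12)
    up = pt.twist_correlation(_rows(period, period * 0.5 + 1.0))
    down = pt.twist_correlation(_rows(period, -period))
    assert up.spearman_rho == pytest.approx(1.0)
    assert down.spearman_rho == pytest.approx(-1.0)
    assert up.label == "positive" and down.label == "negative"


def test_rank_statistic_invariant_under_monotone_rescaling():
    rng = np.random.default_rng(5)
    period = rng.uniform(20.0, 28.0, 40)
    amplitude = np.sin(period / 3.0) + 2.0
    base = pt.twist_correlation(_rows(period, amplitude))
    warped = pt.twist_correlation(_rows(np.exp(period / 10.0), amplitude**3))
    assert warped.spearman_rho == pytest.approx(base.spearman_rho)


def test_constant_amplitude_labelled_none():
    res = pt.twist_correlation(_rows(np.linspace(22, 26, 10), np.ones(10)))
    assert math.isnan(res.spearman_rho) and res.label == "none"


def test_filters_amplitude_and_period_doubling():
    rows = _rows(np.linspace(22, 26, 6), [0.5, 0.05, 0.5, 0.5, 0.5, 0.5])
    rows.loc[4, "period_doubling"] = True
    kept = pt.apply_filters(rows)
    assert len(kept) == 4 and 1 not in kept["member"].values \
        and 4 not in kept["member"].values
    kept_pd = pt.apply_filters(rows, drop_period_doubling=False)
    assert len(kept_pd) == 5
    with pytest.raises(pt.NoOscillatorsRetained):
        pt.apply_filters(_rows([24.0] * 3, [0.01] * 3))


def test_ratio_mode_no_twist_rule():
    period = np.linspace(23.0, 25.0, 10)
    amplitude = np.linspace(1.0, 1.05, 10)          # 5% spread
    res = pt.twist_correlation(_rows(period, amplitude),
                               amplitude_mode="ratio-to-default",
                               default_amplitude=1.0)
    assert res.label == "none"                       # range < 0.1 despite rho=1
    wide = pt.twist_correlation(_rows(period, np.linspace(1.0, 1.3, 10)),
                                amplitude_mode="ratio-to-default",
                                default_amplitude=1.0)
    assert wide.label == "positive"


def test_goodwin_k4_single_parameter_scan_is_monotone(goodwin):
    """Single-parameter oracle: period responds monotonically to k4."""
    values = np.linspace(0.9, 1.1, 5) * goodwin.k4
    specs = [models.with_params(goodwin, k4=float(v)) for v in values]
    rows = pt.ensemble_metrics(specs, var="x")
    periods = rows["period"].to_numpy()
    assert np.all(np.isfinite(periods))
    assert np.all(np.diff(periods) < 0) or np.all(np.diff(periods) > 0)


def test_small_ensemble_uses_permutation_pvalue():
    period = np.linspace(22.0, 26.0, 8)
    res = pt.twist_correlation(_rows(period, period))
    # perfectly concordant n=8: permutation p ~ 2/8! but resampled; must be small
    assert res.p_value < 0.01
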