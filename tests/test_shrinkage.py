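"""Variance model, shrinkage priors, predictions and the means-model baseline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxdose import (
    DEFAULT_SCORES,
    McmcConfig,
    Phenotype,
    PosteriorSummary,
    ShrinkageSpec,
    VarianceParams,
    build_design,
    fit_adjustment_model,
    predict_adjusted_dose,
    regularized_xi_sq,
    sampling_point_variance,
    validate_sampling_points,
    weighted_mean_baseline,
)
from tests.conftest import TEST_MCMC
from tests.test_data import _raw_row


# --- the two analytic formulas --------------------------------------------

def test_sampling_point_variance_arithmetic():
    v = VarianceParams(20.0, 10.0)
    assert sampling_point_variance(4, v) == pytest.approx(400 / 4 + 100)
    big = VarianceParams(55.0, 55.0)
    assert sampling_point_variance(507, big) == pytest.approx(55**2 / 507 + 55**2)
    assert sampling_point_variance(507, big) == pytest.approx(3030.97, abs=0.01)


def test_variance_bounded_below_by_between_component():
    v = VarianceParams(20.0, 10.0)
    n = np.array([1, 10, 1e6, 1e12])
    var = sampling_point_variance(n, v)
    assert np.all(np.diff(var) < 0)
    assert np.all(var > v.sigma_b**2)
    assert var[-1] == pytest.approx(100.0, rel=1e-6)
    with pytest.raises(ValueError):
        sampling_point_variance(0, v)
    with pytest.raises(ValueError):
        VarianceParams(0.0, 10.0)


def test_point_weight_doubles_with_n_but_never_beyond_sigma_b_bound():
    v = VarianceParams(30.0, 15.0)
    n = np.arange(1, 200)
    w = 1.0 / sampling_point_variance(n, v)
    assert np.all(np.diff(w) > 0)
    assert np.all(w < 1.0 / v.sigma_b**2)


def test_regularized_xi_sq_examples():
    assert regularized_xi_sq(1.0, 1.0, 2.0) == pytest.approx(0.8)
    # huge slab: reverts to the plain horseshoe's lambda^2
    assert regularized_xi_sq(3.0, 0.5, 1e8) == pytest.approx(9.0, rel=1e-6)
    with pytest.raises(ValueError):
        regularized_xi_sq(-1.0, 1.0, 1.0)


@settings(max_examples=1000, deadline=None)
@given(
    lam=st.floats(1e-3, 1e3), tau=st.floats(1e-3, 1e3), c=st.floats(1e-3, 1e3)
)
def test_regularized_xi_sq_below_both_caps(lam, tau, c):
    xi2 = regularized_xi_sq(lam, tau, c)
    # strict in exact arithmetic; allow float rounding at extreme ratios
    assert xi2 <= lam**2 * (1 + 1e-12)
    assert xi2 <= (c / tau) ** 2 * (1 + 1e-12)


# --- fits ------------------------------------------------------------------

def test_fixed_regime_with_known_variances_matches_gls_oracle(small_design):
    d, _, _ = small_design
    v = VarianceParams(55.0, 20.0)
    fit = fit_adjustment_model(d, ShrinkageSpec("fixed"), McmcConfig(seed=12), fixed_variance=v)
    A = np.hstack([d.X, d.R])
    w = 1.0 / sampling_point_variance(d.n, v)
    gls = np.linalg.solve((A.T * w) @ A, A.T @ (w * d.y))
    post_mean = np.concatenate([fit.beta_draws.mean(0), fit.theta_draws.mean(0)])
    sd = np.concatenate([fit.beta_draws.std(0), fit.theta_draws.std(0)])
    # exact conditional-Gaussian draws: MC error is sd / sqrt(S)
    mc_se = 3.0 * sd / np.sqrt(fit.beta_draws.shape[0] / 10)
    assert np.all(np.abs(post_mean - gls) <= np.maximum(mc_se, 0.05))
    assert fit.reliable


def test_single_point_substance_is_shrunk_by_every_shrinkage_regime():
    rows = [_raw_row(substance="lonedrug", phenotype="IM", adjustment=-60.0, n=8)]
    points = validate_sampling_points(pd.DataFrame(rows))
    d = build_design(points, confounders=())
    slopes = {}
    for kind in ("fixed", "gaussian", "horseshoe", "reg_horseshoe"):
        fit = fit_adjustment_model(d, ShrinkageSpec(kind), TEST_MCMC.with_seed(3))
        slopes[kind] = float(fit.beta["median"].iloc[0])
    # flat prior on a single sampling point centers at y / score = 60
    assert slopes["fixed"] == pytest.approx(60.0, abs=6.0)
    for kind in ("gaussian", "horseshoe", "reg_horseshoe"):
        assert abs(slopes[kind]) < abs(slopes["fixed"])


def test_student_t_regime_available_and_shrinks(small_design):
    d, _, _ = small_design
    fit_t = fit_adjustment_model(d, ShrinkageSpec("student_t"), TEST_MCMC.with_seed(4))
    fit_f = fit_adjustment_model(d, ShrinkageSpec("fixed"), TEST_MCMC.with_seed(4))
    assert np.isfinite(fit_t.beta["median"]).all()
    assert np.median(np.abs(fit_t.beta["median"])) <= np.median(np.abs(fit_f.beta["median"]))


def test_spec_validation():
    with pytest.raises(ValueError):
        ShrinkageSpec(kind="lasso")
    with pytest.raises(ValueError):
        ShrinkageSpec(tau_scale=-1.0)
    with pytest.raises(ValueError):
        ShrinkageSpec(interval_level=1.5)
    assert ShrinkageSpec("gaussian").tau == 1.0
    assert ShrinkageSpec("horseshoe").tau == 0.1


# --- predictions and the means model --------------------------------------

def _degenerate_posterior(slope_draws: np.ndarray) -> PosteriorSummary:
    beta = slope_draws[:, None]
    q = np.quantile(slope_draws, [0.05, 0.5, 0.95])
    return PosteriorSummary(
        regime="fixed",
        beta=pd.DataFrame({"median": [q[1]], "lower": [q[0]], "upper": [q[2]]}, index=["druga"]),
        theta=pd.DataFrame(columns=["median", "lower", "upper"]),
        variance=pd.DataFrame(columns=["median", "lower", "upper"]),
        shrinkage=pd.DataFrame(columns=["median", "lower", "upper"]),
        diagnostics={},
        beta_draws=beta,
        theta_draws=np.zeros((len(slope_draws), 0)),
        col_index=["druga"],
        interval_level=0.90,
    )


def test_constant_slope_prediction_arithmetic():
    p = _degenerate_posterior(np.full(1000, 20.0))
    pm = predict_adjusted_dose(p, "druga", Phenotype.PM, DEFAULT_SCORES)
    assert pm.dose_pct == pytest.approx(60.0)
    em = predict_adjusted_dose(p, "druga", "EM", DEFAULT_SCORES)
    assert (em.dose_pct, em.lower, em.upper) == (100.0, 100.0, 100.0)


def test_symmetric_draws_give_symmetric_um_interval():
    rng = np.random.default_rng(0)
    draws = 20.0 + rng.normal(0, 5, 200001)
    p = _degenerate_posterior(draws)
    um = predict_adjusted_dose(p, "druga", Phenotype.UM, DEFAULT_SCORES)
    assert um.dose_pct == pytest.approx(100 + 20 * 1.6, abs=0.2)
    assert (um.upper - um.dose_pct) == pytest.approx(um.dose_pct - um.lower, abs=0.3)


def test_unknown_substance_error_lists_known(small_design):
    p = _degenerate_posterior(np.ones(10))
    with pytest.raises(KeyError, match="druga"):
        predict_adjusted_dose(p, "nosuchdrug", 1.0)


def test_weighted_mean_baseline_arithmetic():
    rows = [
        _raw_row(study_id="a", substance="d1", phenotype="PM", adjustment=-30, n=10),
        _raw_row(study_id="b", substance="d1", phenotype="PM", adjustment=-60, n=30),
        _raw_row(study_id="a", substance="d1", phenotype="EM", adjustment=0, n=12),
        _raw_row(study_id="c", substance="d2", phenotype="IM", adjustment=-25, n=7),
    ]
    points = validate_sampling_points(pd.DataFrame(rows))
    out = weighted_mean_baseline(points).set_index(["substance", "phenotype"])
    assert out.loc[("d1", "PM"), "weighted_mean"] == pytest.approx(-52.5)
    assert out.loc[("d1", "PM"), "total_n"] == 40
    assert out.loc[("d1", "PM"), "n_studies"] == 2
    assert out.loc[("d2", "IM"), "weighted_mean"] == pytest.approx(-25.0)
    assert out.loc[("d1", "EM"), "adjusted_dose_pct"] == pytest.approx(100.0)
    # cells never observed are absent, not zero: the means model cannot extrapolate
    assert ("d2", "UM") not in out.index
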