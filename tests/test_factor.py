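"""Phenotype-factor model, activity-score derivation, linearity diagnostics."""

import numpy as np
import pandas as pd
import pytest

from pgxdose import (
    DEFAULT_SCORES,
    GeneratorConfig,
    Phenotype,
    apply_exclusions,
    check_linearity,
    check_log_transform,
    derive_activity_scores,
    fit_phenotype_factor_model,
    generate_dataset,
)
from pgxdose.factor import GroupEstimates
from tests.conftest import TEST_MCMC


def _estimates(groups: dict[str, float], level=0.90, reliable=True, spread=5.0) -> GroupEstimates:
    """Degenerate GroupEstimates with narrow synthetic posteriors."""
    rng = np.random.default_rng(0)
    draws = pd.DataFrame({g: m + spread * rng.standard_normal(4000) for g, m in groups.items()})
    table = pd.DataFrame(
        {
            "median": list(groups.values()),
            "lower": [m - spread for m in groups.values()],
            "upper": [m + spread for m in groups.values()],
        },
        index=list(groups),
    )
    table.loc["EM"] = [0.0, 0.0, 0.0]
    return GroupEstimates(
        groups=table, pooling=table.iloc[:0], variance=table.iloc[:0],
        group_draws=draws, diagnostics={}, interval_level=level, reliable=reliable,
    )


def test_score_derivation_reproduces_allelic_17_average():
    # adjustments scaled so RM/|IM| = 0.70 and UM/|IM| = 1.75
    g = _estimates({"PM": -58.8, "IM": -30.0, "RM": 21.0, "UM": 52.5})
    der = derive_activity_scores(g)
    assert der.raw.loc["RM", "median"] == pytest.approx(0.70)
    assert der.raw.loc["UM", "median"] == pytest.approx(1.75)
    assert der.allelic_17[0] == pytest.approx((0.70 + 1.75 / 2) / 2)  # 0.7875 ~ 0.79
    assert der.final_map[Phenotype.RM] == 0.8
    assert der.final_map[Phenotype.UM] == 1.6
    assert der.final_map[Phenotype.PM] == -2.0  # -1.96 rounded
    assert der.final_map[Phenotype.EM] == 0.0
    assert der.final_map[Phenotype.IM] == -1.0


def test_rm_equal_half_um_gives_exact_allelic_score():
    g = _estimates({"PM": -60.0, "IM": -30.0, "RM": 15.0, "UM": 30.0})
    der = derive_activity_scores(g)
    assert der.allelic_17[0] == pytest.approx(0.5)
    assert der.final_map[Phenotype.UM] == 2 * der.final_map[Phenotype.RM]


def test_scores_invariant_to_rescaling_all_adjustments():
    base = {"PM": -58.8, "IM": -30.0, "RM": 21.0, "UM": 52.5}
    d1 = derive_activity_scores(_estimates(base))
    for k in (0.1, 3.7):
        dk = derive_activity_scores(_estimates({g: k * m for g, m in base.items()}, spread=5.0 * k))
        assert dk.final_map.as_dict() == d1.final_map.as_dict()
        pd.testing.assert_series_equal(dk.raw["median"], d1.raw["median"], atol=1e-9)


def test_derivation_refuses_zero_im_and_unreliable_fit():
    with pytest.raises(ValueError, match="scale undefined"):
        derive_activity_scores(_estimates({"PM": -50.0, "IM": 1e-9, "RM": 15.0, "UM": 30.0}))
    with pytest.raises(RuntimeError, match="non-reliable"):
        derive_activity_scores(
            _estimates({"PM": -50.0, "IM": -25.0, "RM": 15.0, "UM": 30.0}, reliable=False)
        )


def test_factor_model_recovers_group_means(factor_fit, factor_dataset):
    g, truth = factor_fit
    scores = truth.score_map
    slope = float(truth.slopes.iloc[0])  # common slope by construction
    assert g.reliable
    for phen in ("PM", "IM", "RM", "UM"):
        true_mean = slope * scores[phen]
        lo, hi = g.groups.loc[phen, "lower"], g.groups.loc[phen, "upper"]
        width = hi - lo
        assert lo - 0.5 * width <= true_mean <= hi + 0.5 * width, (phen, true_mean, lo, hi)
    assert g.groups.loc["EM", "median"] == 0.0
    # ordering of recovered means follows metabolic activity
    med = g.groups["median"]
    assert med["PM"] < med["IM"] < 0 < med["RM"] < med["UM"]


def test_em_rows_and_absent_levels_are_handled(factor_dataset):
    points, _ = factor_dataset
    with pytest.raises(ValueError, match="EM rows"):
        fit_phenotype_factor_model(points)
    cfg = GeneratorConfig(n_substances=4, seed=77, star17_prob=0.0, studies_min=2, studies_max=3)
    p2, _ = generate_dataset(cfg)
    w2, _ = apply_exclusions(p2, drop_em_rows=True)
    g = fit_phenotype_factor_model(w2, confounders=(), mcmc=TEST_MCMC.with_seed(1))
    assert set(g.absent_levels) == {"RM", "UM"}
    assert "RM" not in g.groups.index


def test_linearity_diagnostics_pass_linear_and_flag_curvature(factor_dataset):
    points, _ = factor_dataset
    working, _ = apply_exclusions(points, drop_em_rows=True)
    lin = check_linearity(working, DEFAULT_SCORES, TEST_MCMC.with_seed(2))
    assert lin.polynomial_identifiable
    assert bool(lin.terms.loc["quadratic", "contains_zero"])
    assert bool(lin.terms.loc["cubic", "contains_zero"])

    curved_cfg = GeneratorConfig(
        n_substances=8, seed=303, prop_nonzero=1.0, slope_mean=25.0, slope_sd=0.0,
        quadratic_coef=-15.0, studies_min=2, studies_max=5, n_min=10, n_max=200,
    )
    cp, _ = generate_dataset(curved_cfg)
    cw, _ = apply_exclusions(cp, drop_em_rows=True)
    lin2 = check_linearity(cw, DEFAULT_SCORES, TEST_MCMC.with_seed(2))
    assert not bool(lin2.terms.loc["quadratic", "contains_zero"])
    assert lin2.terms.loc["quadratic", "median"] < 0


def test_polynomials_unidentifiable_with_two_score_levels():
    cfg = GeneratorConfig(n_substances=5, seed=9, star17_prob=0.0, studies_min=2, studies_max=4)
    points, _ = generate_dataset(cfg)  # PM/IM only: two distinct nonzero scores
    working, _ = apply_exclusions(points, drop_em_rows=True)
    lin = check_linearity(working, DEFAULT_SCORES, TEST_MCMC.with_seed(3))
    assert not lin.polynomial_identifiable
    assert "quadratic" not in lin.terms.index
    assert "slope_17_extra" in lin.terms.index


def test_log_transform_verdicts_follow_the_generative_scale(factor_dataset):
    points, _ = factor_dataset
    working, _ = apply_exclusions(points, drop_em_rows=True)
    raw_verdict = check_log_transform(working, DEFAULT_SCORES, TEST_MCMC.with_seed(5))
    assert raw_verdict.verdict == "raw"

    mcfg = GeneratorConfig(
        n_substances=8, seed=404, prop_nonzero=1.0, slope_mean=40.0, slope_sd=0.0,
        multiplicative=True, studies_min=3, studies_max=6, n_min=5, n_max=60,
    )
    mp, _ = generate_dataset(mcfg)
    mw, _ = apply_exclusions(mp, drop_em_rows=True)
    log_verdict = check_log_transform(mw, DEFAULT_SCORES, TEST_MCMC.with_seed(5))
    assert log_verdict.verdict == "log"
    assert abs(log_verdict.skew_log) < abs(log_verdict.skew_raw)
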