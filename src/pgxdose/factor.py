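"""Phenotype-factor model, activity-score derivation and linearity checks.

The activity scores used by the main adjustment model are themselves
estimated from the data: a factorial model with the phenotype groups as
levels (treatment-coded against EM = 0) gives posterior mean adjustments per
group, which are rescaled so that EM is 0 and IM (one inactive allele) is
exactly -1.  The *17 allelic score is the average of the RM score and half
the UM score.  Preliminary models of this stage include a study-level random
effect; the main adjustment model does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import skew

from .data import (
    ActivityScoreMap,
    ConfounderColumn,
    DEFAULT_SCORES,
    FACTOR_CONFOUNDERS,
    Phenotype,
    PHENOTYPE_ORDER,
)
from .marginal import conditional_coef, marginal_loglik
from .mcmc import (
    McmcConfig,
    log_half_normal,
    log_lognormal_scale,
    rhat_of_chains,
    run_ensemble,
    summarize,
)
from .shrinkage import FLAT_SD, LOG_BOUND, SIGMA_LOG_MU, SIGMA_LOG_SD

logger = logging.getLogger(__name__)

#: Half-normal prior scale for the study random-effect SD (pct points).
STUDY_SD_PRIOR = 50.0


class _MetaRegLogPost:
    """Flat-prior regression with the two-component sampling-point variance.

    Coefficients (and study effects, when present) are marginalized out;
    only [log_sigma_u (if study effect), log_sw, log_sb] are sampled.
    """

    def __init__(self, y: np.ndarray, A: np.ndarray, n: np.ndarray, study_codes: np.ndarray | None):
        self.y = y
        self.inv_n = 1.0 / n
        self.P = A.shape[1]
        self.S = int(study_codes.max()) + 1 if study_codes is not None else 0
        if self.S:
            Z = np.zeros((len(y), self.S))
            Z[np.arange(len(y)), study_codes] = 1.0
            self.U = np.hstack([A, Z])
        else:
            self.U = A
        self.i_su = 0 if self.S else None
        self.i_sw = 1 if self.S else 0
        self.i_sb = self.i_sw + 1
        self.ndim = self.i_sb + 1

    def init_point(self) -> np.ndarray:
        p = np.zeros(self.ndim)
        if self.S:
            p[self.i_su] = np.log(10.0)
        p[self.i_sw] = SIGMA_LOG_MU
        p[self.i_sb] = SIGMA_LOG_MU
        return p

    def invvar(self, p: np.ndarray) -> np.ndarray:
        sw = np.exp(p[:, self.i_sw])[:, None]
        sb = np.exp(p[:, self.i_sb])[:, None]
        return 1.0 / (sw**2 * self.inv_n[None, :] + sb**2)

    def prior_var(self, p: np.ndarray) -> np.ndarray:
        W = p.shape[0]
        vc = np.full((W, self.P), FLAT_SD**2)
        if not self.S:
            return vc
        su2 = np.exp(2.0 * p[:, self.i_su])[:, None]
        return np.hstack([vc, np.broadcast_to(su2, (W, self.S))])

    def __call__(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        lp = np.zeros(p.shape[0])
        bad = np.any(np.abs(p) > LOG_BOUND, axis=1)
        lp[bad] = -np.inf
        ok = ~bad
        if not ok.any():
            return lp
        pok = p[ok]
        prior = log_lognormal_scale(pok[:, self.i_sw], SIGMA_LOG_MU, SIGMA_LOG_SD)
        prior += log_lognormal_scale(pok[:, self.i_sb], SIGMA_LOG_MU, SIGMA_LOG_SD)
        if self.S:
            prior += log_half_normal(pok[:, self.i_su], STUDY_SD_PRIOR)
        lp[ok] = prior + marginal_loglik(self.y, self.U, self.invvar(pok), self.prior_var(pok))
        return lp


@dataclass
class MetaRegressionFit:
    """Coefficient and variance posteriors of one flat-prior meta-regression."""

    coef: pd.DataFrame
    variance: pd.DataFrame
    coef_draws: np.ndarray
    sigma_draws: np.ndarray      # columns: sigma_w, sigma_b
    fitted: np.ndarray           # posterior-mean fit (fixed part only)
    diagnostics: dict
    reliable: bool


def fit_meta_regression(
    y: np.ndarray,
    A: np.ndarray,
    n: np.ndarray,
    names: list[str],
    mcmc: McmcConfig = McmcConfig(),
    study_ids: np.ndarray | None = None,
    level: float = 0.90,
) -> MetaRegressionFit:
    """Fit y = A coef (+ study effect) + eps, eps_i ~ N(0, sw^2/n_i + sb^2).

    The scale parameters are sampled with the coefficients integrated out;
    coefficient draws are exact conditional-Gaussian draws per scale draw.
    """
    codes = None
    if study_ids is not None:
        codes = pd.Categorical(study_ids).codes.astype(int)
    y = np.asarray(y, float)
    A = np.asarray(A, float)
    model = _MetaRegLogPost(y, A, np.asarray(n, float), codes)
    result = run_ensemble(model, model.init_point(), mcmc)
    draws = result.draws
    rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 0xFAC7]).generate_state(1)[0])
    coef_all, coef_means = conditional_coef(y, model.U, model.invvar(draws), model.prior_var(draws), rng)
    coef_draws = coef_all[:, : model.P]
    sigma_draws = np.exp(draws[:, [model.i_sw, model.i_sb]])

    reliable = result.reliable
    messages = list(result.messages)
    mean_chains = coef_means[:, : model.P].reshape(*result.chain.shape[:2], model.P)
    max_rhat = float(np.nanmax(np.concatenate([rhat_of_chains(mean_chains), result.rhat])))
    if max_rhat > mcmc.rhat_threshold:
        reliable = False
        messages.append(f"split-Rhat {max_rhat:.3f} exceeds {mcmc.rhat_threshold} on reported parameters")

    coef = pd.DataFrame(summarize(coef_draws, level), index=names)
    variance = pd.DataFrame(summarize(sigma_draws, level), index=["sigma_w", "sigma_b"])
    fitted = coef_draws.mean(axis=0) @ A.T
    diagnostics = {
        "acceptance_fraction": result.acceptance,
        "max_rhat_reported": max_rhat,
        "min_ess_reported": float(np.nanmin(result.ess)),
        "messages": messages,
    }
    return MetaRegressionFit(coef, variance, coef_draws, sigma_draws, fitted, diagnostics, reliable)


@dataclass
class GroupEstimates:
    """Posterior mean adjustment per phenotype group (EM fixed at 0)."""

    groups: pd.DataFrame          # index: phenotype labels incl. EM; median/lower/upper
    pooling: pd.DataFrame         # pooling-covariate effects (pct points)
    variance: pd.DataFrame        # sigma_w / sigma_b
    group_draws: pd.DataFrame     # posterior draws, one column per non-EM group
    diagnostics: dict
    interval_level: float
    reliable: bool = True
    absent_levels: list[str] = field(default_factory=list)


def fit_phenotype_factor_model(
    points: pd.DataFrame,
    confounders: tuple[ConfounderColumn, ...] = FACTOR_CONFOUNDERS,
    mcmc: McmcConfig = McmcConfig(),
    random_study: bool = True,
    level: float = 0.90,
) -> GroupEstimates:
    """Estimate per-phenotype mean adjustments with pooling confounders.

    Expects EM rows and non-substrate substances already removed.  Phenotype
    levels with no rows are reported absent.  A non-converged fit is flagged
    and refused by downstream score derivation.
    """
    if (points["phenotype"] == Phenotype.EM.value).any():
        raise ValueError("EM rows must be removed before fitting the factor model")
    levels = [p.value for p in PHENOTYPE_ORDER if p != Phenotype.EM]
    present = [g for g in levels if (points["phenotype"] == g).any()]
    absent = [g for g in levels if g not in present]
    if absent:
        logger.warning("phenotype level(s) with no data reported absent: %s", absent)

    A_groups = np.column_stack(
        [(points["phenotype"] == g).to_numpy(dtype=float) for g in present]
    )
    conf_cols = [c.values(points, DEFAULT_SCORES) for c in confounders]
    A = np.column_stack([A_groups, *conf_cols]) if conf_cols else A_groups
    names = present + [c.label for c in confounders]

    fit = fit_meta_regression(
        points["adjustment"].to_numpy(float),
        A,
        points["n"].to_numpy(float),
        names,
        mcmc,
        study_ids=points["study_id"].to_numpy() if random_study else None,
        level=level,
    )
    groups = fit.coef.loc[present].copy()
    groups.loc["EM"] = [0.0, 0.0, 0.0]
    groups = groups.reindex([p.value for p in PHENOTYPE_ORDER if p.value in groups.index])
    pooling = fit.coef.loc[[c.label for c in confounders]] if confounders else fit.coef.iloc[:0]
    group_draws = pd.DataFrame(fit.coef_draws[:, : len(present)], columns=present)
    return GroupEstimates(
        groups=groups,
        pooling=pooling,
        variance=fit.variance,
        group_draws=group_draws,
        diagnostics=fit.diagnostics,
        interval_level=level,
        reliable=fit.reliable,
        absent_levels=absent,
    )


@dataclass
class ScoreDerivation:
    """EM-anchored, IM-scaled activity scores and the *17 allelic score."""

    raw: pd.DataFrame             # per-group score: median/lower/upper (ratio draws)
    allelic_17: tuple[float, float, float]   # median, lower, upper
    final_map: ActivityScoreMap


def derive_activity_scores(g: GroupEstimates, tol: float = 1e-6) -> ScoreDerivation:
    """Rescale group adjustments into activity scores.

    score_g = (median adjustment of g) / |median adjustment of IM|, sign
    preserved, so IM is exactly -1 and EM exactly 0.  The *17 allelic score
    averages the per-allele effect seen in RM (one *17) and UM (two *17):
    mean(score_RM, score_UM / 2).  The final working map rounds to one
    decimal and enforces UM = 2 x RM.
    """
    if not g.reliable:
        raise RuntimeError("refusing to derive scores from a non-reliable factor fit")
    if "IM" not in g.group_draws.columns:
        raise ValueError("IM group absent; scale undefined")
    im_med = float(g.groups.loc["IM", "median"])
    if abs(im_med) < tol:
        raise ValueError("IM median adjustment is ~0; activity-score scale undefined")

    a = (1.0 - g.interval_level) / 2.0
    rows = {}
    point = {}
    for grp in g.group_draws.columns:
        ratio = g.group_draws[grp].to_numpy() / np.abs(g.group_draws["IM"].to_numpy())
        lo, hi = np.quantile(ratio, [a, 1.0 - a])
        med = float(g.groups.loc[grp, "median"]) / abs(im_med)
        point[grp] = med
        rows[grp] = [med, lo, hi]
    rows["IM"] = [-1.0, -1.0, -1.0]
    point["IM"] = -1.0
    rows["EM"] = [0.0, 0.0, 0.0]
    raw = pd.DataFrame.from_dict(rows, orient="index", columns=["median", "lower", "upper"])
    raw = raw.reindex([p.value for p in PHENOTYPE_ORDER if p.value in raw.index])

    if not {"RM", "UM"} <= set(point):
        raise ValueError("RM and UM estimates are required for the *17 allelic score")
    a17 = 0.5 * (point["RM"] + point["UM"] / 2.0)
    a17_draws = 0.5 * (
        g.group_draws["RM"].to_numpy() + g.group_draws["UM"].to_numpy() / 2.0
    ) / np.abs(g.group_draws["IM"].to_numpy())
    a17_lo, a17_hi = np.quantile(a17_draws, [a, 1.0 - a])

    rm_final = round(a17, 1)
    final_map = ActivityScoreMap(
        {
            Phenotype.PM: round(point["PM"], 1) if "PM" in point else -2.0,
            Phenotype.IM: -1.0,
            Phenotype.EM: 0.0,
            Phenotype.RM: rm_final,
            Phenotype.UM: 2.0 * rm_final,
        }
    )
    return ScoreDerivation(raw=raw, allelic_17=(float(a17), float(a17_lo), float(a17_hi)), final_map=final_map)


@dataclass
class LinearityDiagnostics:
    """Polynomial and separate-*17-slope checks of the linear score effect."""

    terms: pd.DataFrame            # quadratic/cubic/slope_17_extra: median/lower/upper/contains_zero
    polynomial_identifiable: bool


def check_linearity(
    points: pd.DataFrame,
    scores: ActivityScoreMap,
    mcmc: McmcConfig = McmcConfig(),
    confounders: tuple[ConfounderColumn, ...] = (),
    level: float = 0.90,
) -> LinearityDiagnostics:
    """Test departures from a linear activity-score effect on the whole dataset.

    Fits (a) slope + quadratic + cubic score terms and (b) slope plus an
    extra slope for *17-carrying phenotypes (RM/UM).  Terms whose credibility
    interval contains zero indicate no detectable departure from linearity.
    """
    s = points["phenotype"].map(lambda p: scores[p]).to_numpy(float)
    y = points["adjustment"].to_numpy(float)
    n = points["n"].to_numpy(float)
    study = points["study_id"].to_numpy()
    conf = [c.values(points, scores) for c in confounders]
    conf_names = [c.label for c in confounders]

    rows = {}
    identifiable = len(np.unique(s[s != 0])) >= 3
    if identifiable:
        A = np.column_stack([s, s**2, s**3, *conf])
        fit = fit_meta_regression(y, A, n, ["slope", "quadratic", "cubic", *conf_names],
                                  mcmc, study_ids=study, level=level)
        for term in ("quadratic", "cubic"):
            r = fit.coef.loc[term]
            rows[term] = [r["median"], r["lower"], r["upper"]]
    else:
        logger.warning("fewer than 3 distinct nonzero activity scores: polynomial terms unidentifiable")

    is17 = points["phenotype"].isin(["RM", "UM"]).to_numpy(float)
    A2 = np.column_stack([s, s * is17, *conf])
    fit2 = fit_meta_regression(y, A2, n, ["slope", "slope_17_extra", *conf_names],
                               mcmc.with_seed(mcmc.seed + 1), study_ids=study, level=level)
    r = fit2.coef.loc["slope_17_extra"]
    rows["slope_17_extra"] = [r["median"], r["lower"], r["upper"]]

    terms = pd.DataFrame.from_dict(rows, orient="index", columns=["median", "lower", "upper"])
    terms["contains_zero"] = (terms["lower"] <= 0.0) & (terms["upper"] >= 0.0)
    return LinearityDiagnostics(terms=terms, polynomial_identifiable=identifiable)


@dataclass
class TransformVerdict:
    """Raw- vs log-scale comparison of the adjustment model residuals."""

    skew_raw: float
    skew_log: float
    log_quadratic: tuple[float, float, float]   # median, lower, upper on the log branch
    verdict: str                                # "raw" or "log"
    n_dropped_log: int


#: |skewness| above this counts as residual asymmetry.
SKEW_THRESHOLD = 0.5


def check_log_transform(
    points: pd.DataFrame,
    scores: ActivityScoreMap,
    mcmc: McmcConfig = McmcConfig(),
    level: float = 0.90,
) -> TransformVerdict:
    """Decide whether adjustments should be modelled on the raw or log scale.

    The raw branch models percentage-point adjustments; the log branch models
    log(adjusted dose / 100) (rows with non-positive adjusted dose are
    dropped with a warning).  Each branch fits a linear score effect; the
    verdict favors the scale with the more symmetric standardized residuals,
    unless the log branch loses linearity (quadratic term interval excluding
    zero), in which case the raw scale is retained.
    """
    s = points["phenotype"].map(lambda p: scores[p]).to_numpy(float)
    y = points["adjustment"].to_numpy(float)
    n = points["n"].to_numpy(float)
    study = points["study_id"].to_numpy()

    def _branch(y_b, s_b, n_b, study_b, seed, quad):
        cols = [s_b, s_b**2] if quad else [s_b]
        names = ["slope", "quadratic"] if quad else ["slope"]
        fit = fit_meta_regression(y_b, np.column_stack(cols), n_b, names,
                                  mcmc.with_seed(seed), study_ids=study_b, level=level)
        sw, sb = fit.sigma_draws.mean(axis=0)
        sd = np.sqrt(sw**2 / n_b + sb**2)
        resid = (y_b - fit.fitted) / sd
        return fit, float(skew(resid))

    _, skew_raw = _branch(y, s, n, study, mcmc.seed + 11, quad=False)

    pos = (100.0 + y) > 0
    dropped = int((~pos).sum())
    if dropped:
        logger.warning("dropping %d row(s) with non-positive adjusted dose from the log branch", dropped)
    ylog = 100.0 * np.log((100.0 + y[pos]) / 100.0)   # scaled so units stay comparable
    fit_log, skew_log = _branch(ylog, s[pos], n[pos], study[pos], mcmc.seed + 12, quad=True)
    q = fit_log.coef.loc["quadratic"]
    log_linear = bool(q["lower"] <= 0.0 <= q["upper"])

    if (abs(skew_log) < abs(skew_raw) - 1e-12) and log_linear and abs(skew_raw) > SKEW_THRESHOLD:
        verdict = "log"
    else:
        verdict = "raw"
    return TransformVerdict(
        skew_raw=skew_raw,
        skew_log=skew_log,
        log_quadratic=(float(q["median"]), float(q["lower"]), float(q["upper"])),
        verdict=verdict,
        n_dropped_log=dropped,
    )
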