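"""Synthetic sampling-point datasets with known ground truth.

The generator reproduces the statistical structure the analysis assumes: a
population of substances of which only some are CYP2C19 substrates (sparse
per-substance slopes), between one and a handful of studies per substance,
group sample sizes spanning tiny pharmacokinetic panels to large TDM cohorts
(log-uniform over 1-507), two-component residual noise sigma_w^2/n +
sigma_b^2, and study-design pooling flags with their biasing effects (the
RM-pooling bias defaults to +38 percentage points).  Studies performed
before *17 genotyping report only PM/IM rows; EM reference rows are emitted
with adjustment 0 to exercise the exclusion logic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .data import COLUMNS, DEFAULT_SCORES, ActivityScoreMap, Phenotype, validate_sampling_points
from .shrinkage import PosteriorSummary


class GeneratorConfig(BaseModel):
    """Study conditions of the synthetic benchmark."""

    n_substances: int = Field(20, ge=1)
    prop_nonzero: float = Field(0.5, ge=0.0, le=1.0)
    slope_mean: float = 20.0          # pct points of adjustment per activity unit
    slope_sd: float = Field(10.0, ge=0.0)
    sigma_w: float = Field(55.0, gt=0.0)   # near the log-normal(4, 0.25) prior median
    sigma_b: float = Field(20.0, gt=0.0)
    studies_min: int = Field(1, ge=1)
    studies_max: int = Field(8, ge=1)
    n_min: int = Field(1, ge=1)
    n_max: int = Field(507, ge=1)
    pm_prob: float = Field(0.8, ge=0.0, le=1.0)
    star17_prob: float = Field(0.5, ge=0.0, le=1.0)   # study genotyped *17 at all
    rm_prob: float = Field(0.8, ge=0.0, le=1.0)       # RM row given *17 genotyping
    um_prob: float = Field(0.5, ge=0.0, le=1.0)       # UM row given *17 genotyping
    conf_probs: dict[str, float] = Field(
        default_factory=lambda: {"pool_rm17": 0.2, "pool_im17": 0.2}
    )
    conf_effects: dict[str, float] = Field(
        default_factory=lambda: {"pool_rm17": 38.0, "pool_im17": 2.0}
    )
    score_map: dict[str, float] = Field(
        default_factory=lambda: DEFAULT_SCORES.as_dict()
    )
    quadratic_coef: float = 0.0       # curvature injection for diagnostics tests
    multiplicative: bool = False      # log-normal (multiplicative) noise instead
    emit_em_rows: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _ranges(self) -> "GeneratorConfig":
        if self.studies_max < self.studies_min or self.n_max < self.n_min:
            raise ValueError("empty studies/sample-size range")
        for k, v in self.conf_probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"conf_probs[{k}] outside [0, 1]")
        return self


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated dataset."""

    slopes: pd.Series             # per-substance true slope (0 for non-substrates)
    conf_effects: dict[str, float]
    sigma_w: float
    sigma_b: float
    score_map: ActivityScoreMap

    def as_dict(self) -> dict:
        return {
            "slopes": {k: float(v) for k, v in self.slopes.items()},
            "conf_effects": self.conf_effects,
            "sigma_w": self.sigma_w,
            "sigma_b": self.sigma_b,
            "score_map": self.score_map.as_dict(),
        }


def generate_dataset(cfg: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic sampling-point table plus its ground truth.

    Deterministic under (cfg, seed): identical configs produce bit-identical
    tables.  Substance d's rows follow y = slope_d * score(phenotype)
    [+ quadratic curvature] + pooling effects + e with e ~ N(0, sw^2/n + sb^2)
    (or multiplicatively on the adjusted-dose scale when configured).
    """
    rng = np.random.default_rng(cfg.seed)
    scores = ActivityScoreMap({Phenotype(k): v for k, v in cfg.score_map.items()})

    nonzero = rng.random(cfg.n_substances) < cfg.prop_nonzero
    slopes = np.where(nonzero, rng.normal(cfg.slope_mean, cfg.slope_sd, cfg.n_substances), 0.0)
    names = [f"drug{d:03d}" for d in range(cfg.n_substances)]
    truth = SyntheticTruth(
        slopes=pd.Series(slopes, index=names),
        conf_effects=dict(cfg.conf_effects),
        sigma_w=cfg.sigma_w,
        sigma_b=cfg.sigma_b,
        score_map=scores,
    )

    rows: list[dict] = []
    study_counter = 0
    for d, name in enumerate(names):
        n_studies = int(rng.integers(cfg.studies_min, cfg.studies_max + 1))
        for _ in range(n_studies):
            study_counter += 1
            study_id = f"study{study_counter:04d}"
            knows_17 = rng.random() < cfg.star17_prob
            phens = [Phenotype.IM]
            if rng.random() < cfg.pm_prob:
                phens.append(Phenotype.PM)
            if knows_17:
                if rng.random() < cfg.rm_prob:
                    phens.append(Phenotype.RM)
                if rng.random() < cfg.um_prob:
                    phens.append(Phenotype.UM)
            flags = {f: int(rng.random() < p) for f, p in cfg.conf_probs.items()}
            for f in ("pool_rm17", "pool_im17", "pool_em2", "pool_em17"):
                flags.setdefault(f, 0)
            if not knows_17:
                flags["pool_rm17"] = 0
                flags["pool_im17"] = 0
            pk = rng.choice(["AUC", "CL", "Css", "MR"], p=[0.35, 0.25, 0.35, 0.05])
            pop = rng.choice(["healthy", "patients"])
            dosing = rng.choice(["SD", "MD"])
            idm = rng.choice(["phenotyping", "genotyping"], p=[0.3, 0.7])

            design = {
                **flags,
                "pk_param": pk,
                "population": pop,
                "dosing": dosing,
                "id_method": idm,
            }
            if cfg.emit_em_rows:
                n_em = _draw_n(rng, cfg)
                rows.append(
                    {"study_id": study_id, "substance": name, "phenotype": "EM",
                     "adjustment": 0.0, "n": n_em, **design}
                )
            for phen in phens:
                s = scores[phen]
                n_i = _draw_n(rng, cfg)
                mean = slopes[d] * s + cfg.quadratic_coef * s**2
                if phen is Phenotype.RM and flags["pool_rm17"]:
                    mean += cfg.conf_effects.get("pool_rm17", 0.0)
                if phen is Phenotype.IM and flags["pool_im17"]:
                    mean += cfg.conf_effects.get("pool_im17", 0.0)
                sd = np.sqrt(cfg.sigma_w**2 / n_i + cfg.sigma_b**2)
                if cfg.multiplicative:
                    # log-linear effects with log-normal noise: the slope acts
                    # as approximate percent change per activity unit on the
                    # log-dose scale, so the raw scale is right-skewed and
                    # curved while the log scale is linear and symmetric
                    log_dev = (slopes[d] * s + cfg.quadratic_coef * s**2) / 100.0
                    if phen is Phenotype.RM and flags["pool_rm17"]:
                        log_dev += cfg.conf_effects.get("pool_rm17", 0.0) / 100.0
                    if phen is Phenotype.IM and flags["pool_im17"]:
                        log_dev += cfg.conf_effects.get("pool_im17", 0.0) / 100.0
                    y = 100.0 * np.exp(log_dev + rng.normal(0.0, sd / 100.0)) - 100.0
                else:
                    y = mean + rng.normal(0.0, sd)
                rows.append(
                    {"study_id": study_id, "substance": name, "phenotype": phen.value,
                     "adjustment": float(y), "n": n_i, **design}
                )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return validate_sampling_points(df), truth


def _draw_n(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    """Log-uniform group sample size over [n_min, n_max]."""
    lo, hi = np.log(cfg.n_min), np.log(cfg.n_max + 1)
    return int(np.exp(rng.uniform(lo, hi)))


def benchmark_dataset(seed: int, n_substances: int = 20) -> tuple[pd.DataFrame, SyntheticTruth]:
    """The shrinkage benchmark: default study conditions plus two probes.

    On top of the default generator (mixed study counts, 50% non-substrates)
    two designed substances are appended so the benchmark always contains
    both evidence extremes regardless of seed:

    * ``probe_sparse`` — a single small study (one IM group, n = 8) reporting
      a large adjustment (-60), the classic case a shrinkage prior should
      pull toward zero;
    * ``probe_dense``  — eight studies with large groups (n = 300) of a true
      substrate (slope 25), where every regime should agree.
    """
    cfg = GeneratorConfig(n_substances=n_substances, seed=seed)
    points, truth = generate_dataset(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBE7C]).generate_state(1)[0])
    scores = truth.score_map

    extra: list[dict] = []
    design = {"pool_rm17": 0, "pool_im17": 0, "pool_em2": 0, "pool_em17": 0,
              "pk_param": "AUC", "population": "healthy", "dosing": "SD",
              "id_method": "genotyping"}
    extra.append({"study_id": "probe_sparse_s1", "substance": "probe_sparse",
                  "phenotype": "IM", "adjustment": -60.0, "n": 8, **design})
    dense_slope = 25.0
    for k in range(8):
        sid = f"probe_dense_s{k + 1}"
        for phen in (Phenotype.PM, Phenotype.IM, Phenotype.RM):
            s = scores[phen]
            sd = np.sqrt(truth.sigma_w**2 / 300 + truth.sigma_b**2)
            extra.append({"study_id": sid, "substance": "probe_dense",
                          "phenotype": phen.value,
                          "adjustment": float(dense_slope * s + rng.normal(0.0, sd)),
                          "n": 300, **design})
    points = pd.concat([points, pd.DataFrame(extra, columns=COLUMNS)], ignore_index=True)
    slopes = pd.concat([truth.slopes, pd.Series({"probe_sparse": 60.0, "probe_dense": dense_slope})])
    truth = SyntheticTruth(slopes=slopes, conf_effects=truth.conf_effects,
                           sigma_w=truth.sigma_w, sigma_b=truth.sigma_b, score_map=scores)
    return validate_sampling_points(points), truth


def recovery_report(truth: SyntheticTruth, fit: PosteriorSummary) -> dict:
    """Compare a fitted adjustment model against the generator's truth.

    Reports per-substance bias, absolute error and interval coverage, plus
    aggregate RMSE, coverage rate and sign-error rate, split by whether the
    true slope is zero.  sigma_w / sigma_b recovery is included when the fit
    estimated them.
    """
    missing = [s for s in fit.col_index if s not in truth.slopes.index]
    if missing:
        raise ValueError(f"fit substances not in truth index: {missing}")
    rows = []
    for s in fit.col_index:
        true = float(truth.slopes[s])
        med = float(fit.beta.loc[s, "median"])
        lo, hi = float(fit.beta.loc[s, "lower"]), float(fit.beta.loc[s, "upper"])
        rows.append(
            {
                "substance": s,
                "true_slope": true,
                "median": med,
                "bias": med - true,
                "abs_error": abs(med - true),
                "covered": lo <= true <= hi,
                "sign_error": (true != 0.0) and (np.sign(med) != np.sign(true)),
                "interval_width": hi - lo,
            }
        )
    per = pd.DataFrame(rows).set_index("substance")
    nz = per[per["true_slope"] != 0.0]
    zero = per[per["true_slope"] == 0.0]
    report = {
        "per_substance": per,
        "rmse": float(np.sqrt(np.mean(per["bias"] ** 2))),
        "coverage": float(per["covered"].mean()),
        "coverage_nonzero": float(nz["covered"].mean()) if len(nz) else float("nan"),
        "coverage_zero": float(zero["covered"].mean()) if len(zero) else float("nan"),
        "sign_error_rate": float(nz["sign_error"].mean()) if len(nz) else 0.0,
    }
    if len(fit.variance):
        report["sigma_w_median"] = float(fit.variance.loc["sigma_w", "median"])
        report["sigma_b_median"] = float(fit.variance.loc["sigma_b", "median"])
        report["sigma_w_true"] = truth.sigma_w
        report["sigma_b_true"] = truth.sigma_b
    return report
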