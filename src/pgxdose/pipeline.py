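"""End-to-end orchestration: load -> exclude -> scores -> screen -> fit -> predict.

The pipeline mirrors the analysis stages of the underlying study: estimate
phenotype-group adjustments and derive activity scores (after removing
non-substrate drugs and RM-pooled studies), screen study properties for
slope-level confounding, then fit the per-substance adjustment model under
the requested prior regimes and tabulate slopes, adjusted doses and the
weighted-mean baseline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .data import (
    ActivityScoreMap,
    DEFAULT_CONFOUNDERS,
    DEFAULT_SCORES,
    NON_SUBSTRATES,
    Phenotype,
    apply_exclusions,
    build_design,
    load_sampling_points,
)
from .factor import (
    check_linearity,
    check_log_transform,
    derive_activity_scores,
    fit_meta_regression,
    fit_phenotype_factor_model,
)
from .mcmc import McmcConfig, derive_seeds
from .shrinkage import (
    PosteriorSummary,
    ShrinkageSpec,
    compare_models,
    predict_adjusted_dose,
    weighted_mean_baseline,
)
from .simulate import GeneratorConfig, generate_dataset, recovery_report

logger = logging.getLogger(__name__)

#: Binary contrast used when screening each study property (1-level vs rest).
PROPERTY_CODES = {
    "pool_rm17": lambda df: df["pool_rm17"].to_numpy(float),
    "pool_im17": lambda df: df["pool_im17"].to_numpy(float),
    "pool_em2": lambda df: df["pool_em2"].to_numpy(float),
    "pool_em17": lambda df: df["pool_em17"].to_numpy(float),
    "pk_param": lambda df: df["pk_param"].isin(["AUC", "CL"]).to_numpy(float),
    "population": lambda df: (df["population"] == "healthy").to_numpy(float),
    "dosing": lambda df: (df["dosing"] == "SD").to_numpy(float),
    "id_method": lambda df: (df["id_method"] == "phenotyping").to_numpy(float),
}


def screen_study_properties(
    points: pd.DataFrame,
    scores: ActivityScoreMap,
    properties: list[str],
    mcmc: McmcConfig = McmcConfig(),
    level: float = 0.90,
) -> pd.DataFrame:
    """Estimate, per study property, its interaction with the activity-score
    slope (percentage points of adjustment per activity-score unit).

    Each property is screened in its own model y = b*s + g*(s x property) +
    eps; a property whose interval excludes zero is recommended for
    inclusion.  The RM-pooling group-level effect is always retained in the
    final confounder set regardless of this screen.
    """
    unknown = [p for p in properties if p not in PROPERTY_CODES]
    if unknown:
        raise ValueError(f"unknown propert(ies) {unknown}; valid: {sorted(PROPERTY_CODES)}")
    s = points["phenotype"].map(lambda p: scores[p]).to_numpy(float)
    y = points["adjustment"].to_numpy(float)
    n = points["n"].to_numpy(float)
    study = points["study_id"].to_numpy()
    seeds = derive_seeds(mcmc.seed, len(properties))
    rows = []
    for prop, seed in zip(properties, seeds):
        code = PROPERTY_CODES[prop](points)
        inter = s * code
        if np.allclose(inter, 0.0) or np.allclose(inter, inter.mean()):
            logger.warning("property %s has no contrast in these data; skipped", prop)
            continue
        fit = fit_meta_regression(
            y, np.column_stack([s, inter]), n, ["slope", "interaction"],
            mcmc.with_seed(seed), study_ids=study, level=level,
        )
        r = fit.coef.loc["interaction"]
        excl_zero = not (r["lower"] <= 0.0 <= r["upper"])
        rows.append(
            {
                "property": prop,
                "interaction": float(r["median"]),
                "lower": float(r["lower"]),
                "upper": float(r["upper"]),
                "recommendation": "include" if excl_zero else "exclude",
                "reliable": fit.reliable,
            }
        )
    return pd.DataFrame(rows)


class PipelineConfig(BaseModel):
    """One run of the full pipeline."""

    input_csv: str | None = None
    simulate: GeneratorConfig | None = None
    drop_substances: list[str] = Field(default_factory=lambda: list(NON_SUBSTRATES))
    score_source: str = "derived"            # "derived" | "fixed"
    fixed_scores: dict[str, float] = Field(default_factory=lambda: DEFAULT_SCORES.as_dict())
    regimes: list[str] = Field(default_factory=lambda: ["fixed", "gaussian", "horseshoe", "reg_horseshoe"])
    interval_level: float = 0.90
    seed: int = 0
    run_diagnostics: bool = True
    screen_properties: list[str] = Field(default_factory=lambda: ["pool_em2", "pool_em17", "pk_param", "population", "dosing"])
    n_steps: int = 1500
    n_burn: int = 1500
    output_dir: str = "results/pipeline"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if not self.regimes:
            raise ValueError("at least one prior regime must be named")
        if self.input_csv is None and self.simulate is None:
            raise ValueError("either input_csv or a simulate config is required")
        if self.score_source not in ("derived", "fixed"):
            raise ValueError("score_source must be 'derived' or 'fixed'")
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write tables plus a manifest to the run directory.

    Returns the manifest.  A failed stage raises, aborting downstream stages;
    non-reliable fits are flagged in the manifest and the comparison table.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    mcmc = McmcConfig(n_steps=cfg.n_steps, n_burn=cfg.n_burn, seed=cfg.seed)
    seeds = derive_seeds(cfg.seed, 6)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }

    # -- stage 1: data ------------------------------------------------------
    truth = None
    if cfg.input_csv is not None:
        points = load_sampling_points(cfg.input_csv)
    else:
        points, truth = generate_dataset(cfg.simulate)
        manifest["generator_seed"] = cfg.simulate.seed
    manifest["stages"]["load"] = {"rows": len(points), "substances": int(points["substance"].nunique())}

    # -- stage 2: exclusions ------------------------------------------------
    working, log = apply_exclusions(points, drop_em_rows=True, drop_substances=cfg.drop_substances)
    (out / "exclusions.json").write_text(json.dumps(log, indent=2))
    manifest["stages"]["exclusions"] = {"rows": len(working), "log": log}

    # -- stage 3: activity scores -------------------------------------------
    if cfg.score_source == "derived":
        unpooled, _ = apply_exclusions(working, drop_pool_rm17=True)
        groups = fit_phenotype_factor_model(unpooled, mcmc=mcmc.with_seed(seeds[0]), level=cfg.interval_level)
        derivation = derive_activity_scores(groups)
        score_map = derivation.final_map
        table2 = derivation.raw.copy()
        table2.loc["*17_allele"] = list(derivation.allelic_17)
        table2.to_csv(out / "activity_scores.csv")
        groups.groups.to_csv(out / "group_estimates.csv")
        groups.pooling.to_csv(out / "pooling_effects.csv")
        manifest["stages"]["activity_scores"] = {
            "final_map": score_map.as_dict(),
            "allelic_17": derivation.allelic_17[0],
            "reliable": groups.reliable,
            **{k: v for k, v in groups.diagnostics.items() if k != "messages"},
        }
    else:
        score_map = ActivityScoreMap({Phenotype(k): v for k, v in cfg.fixed_scores.items()})
        manifest["stages"]["activity_scores"] = {"final_map": score_map.as_dict(), "source": "fixed"}

    # -- stage 4: diagnostics -----------------------------------------------
    if cfg.run_diagnostics:
        lin = check_linearity(working, score_map, mcmc=mcmc.with_seed(seeds[1]), level=cfg.interval_level)
        trans = check_log_transform(working, score_map, mcmc=mcmc.with_seed(seeds[2]), level=cfg.interval_level)
        diag = {
            "linearity": lin.terms.reset_index().to_dict(orient="records"),
            "polynomial_identifiable": lin.polynomial_identifiable,
            "transform": {
                "skew_raw": trans.skew_raw,
                "skew_log": trans.skew_log,
                "verdict": trans.verdict,
            },
        }
        (out / "diagnostics.json").write_text(json.dumps(diag, indent=2, default=float))
        manifest["stages"]["diagnostics"] = {"transform_verdict": trans.verdict}

    # -- stage 5: property screening ----------------------------------------
    if cfg.screen_properties:
        screen = screen_study_properties(working, score_map, cfg.screen_properties,
                                         mcmc=mcmc.with_seed(seeds[3]), level=cfg.interval_level)
        screen.to_csv(out / "screening.csv", index=False)
        manifest["stages"]["screening"] = screen.to_dict(orient="records")

    # -- stage 6: four-regime fits ------------------------------------------
    d = build_design(working, score_map, DEFAULT_CONFOUNDERS)
    specs = [ShrinkageSpec(kind=r, interval_level=cfg.interval_level) for r in cfg.regimes]
    if len(specs) == 1:
        fit = _single_fit(d, specs[0], mcmc.with_seed(seeds[4]))
        fits = {specs[0].kind: fit}
        table = fit.beta.reset_index(names="substance").assign(regime=specs[0].kind)
    else:
        table, fits = compare_models(d, specs, mcmc.with_seed(seeds[4]), baseline_points=working)
    table.to_csv(out / "comparison.csv", index=False)
    manifest["stages"]["fits"] = {k: f.diagnostics for k, f in fits.items()}

    # -- stage 7: predictions and baseline ----------------------------------
    baseline = weighted_mean_baseline(working)
    baseline.to_csv(out / "weighted_mean_baseline.csv", index=False)
    pred_rows = []
    for regime, fit in fits.items():
        for substance in fit.col_index:
            for phen in (Phenotype.PM, Phenotype.IM, Phenotype.RM, Phenotype.UM):
                p = predict_adjusted_dose(fit, substance, phen, score_map)
                pred_rows.append(
                    {"substance": substance, "phenotype": phen.value, "regime": regime,
                     "adjusted_dose_pct": p.dose_pct, "lower": p.lower, "upper": p.upper}
                )
    pd.DataFrame(pred_rows).to_csv(out / "adjusted_doses.csv", index=False)

    if truth is not None and len(fits):
        last = fits[list(fits)[-1]]
        rec = recovery_report(truth, last)
        manifest["recovery"] = {k: v for k, v in rec.items() if k != "per_substance"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    logger.info("pipeline complete; outputs in %s", out)
    return manifest


def _single_fit(d, spec, mcmc) -> PosteriorSummary:
    from .shrinkage import fit_adjustment_model

    return fit_adjustment_model(d, spec, mcmc)
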