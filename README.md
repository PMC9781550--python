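# pgxdose

Bayesian estimation of pharmacogenetic dose adjustments for CYP2C19
metabolizer phenotypes, with global–local shrinkage across substances.

## The problem

Patients differ in CYP2C19 enzyme activity: poor metabolizers (PM, two null
alleles), intermediate (IM, one null), extensive/normal (EM, the
reference), rapid (RM, one \*17 allele) and ultrarapid (UM, \*17/\*17).
Published pharmacokinetic studies report, per drug and phenotype group, the
percent dose adjustment that would equalize exposure against EM — but the
evidence is sparse (often one small study per drug), heterogeneous in
design (genotype pooling, AUC vs clearance vs steady-state concentration,
patients vs healthy volunteers), and group sizes run from n = 1 to several
hundred.  Averaging each phenotype–substance cell separately, as
traditional weighted-means recommendations do, overfits small samples and
cannot extrapolate to unobserved groups.

`pgxdose` instead models each sampling point (one study × substance ×
phenotype adjustment, in percentage points vs EM) as

    y = X β + R θ + ε,        Var(ε_i) = σ_w²/n_i + σ_b²

with no intercept (EM ≡ 0, adjusted dose = 100 + adjustment), one slope
β_j per substance on a data-derived *activity score* (EM = 0, IM = −1,
PM ≈ −2, RM ≈ 0.8, UM ≈ 1.6), unshrunk confounder effects θ (genotype
pooling bias), and a sample-size-weighted two-component residual variance.
The slopes are fit under four priors — flat ("fixed effects"), Gaussian
random effect `β_j ~ N(0, τ²), τ ~ C⁺(0,1)`, the horseshoe
`β_j ~ N(0, τ²λ_j²), τ ~ C⁺(0,0.1), λ_j ~ C⁺(0,1)`, and the regularized
horseshoe with slab `ξ_j² = c²λ_j²/(c² + τ²λ_j²), c ~ t⁺(0, 2.5, 8)` — so
that poorly-evidenced slopes are shrunk toward zero while well-evidenced
ones are left alone.  One slope per substance means evidence from any
phenotype group informs predictions for all of them, including groups no
study observed.

It is written for biostatisticians and clinical-pharmacology researchers
who want to reproduce, stress-test or extend this estimation strategy; all
fits run on plain NumPy log-posteriors (coefficients marginalized
analytically, scales sampled with emcee), no probabilistic-programming
framework required.  See `docs/methods.md` for the full model account.

## Worked example

```python
from pgxdose import *
from pgxdose.simulate import benchmark_dataset

points, truth = benchmark_dataset(seed=1)          # 22 substances incl. 2 probes
working, _ = apply_exclusions(points, drop_em_rows=True)
d = build_design(working)                          # y, X, R, n
specs = [ShrinkageSpec(k) for k in ("fixed", "gaussian", "horseshoe", "reg_horseshoe")]
table, fits = compare_models(d, specs, McmcConfig(seed=1), baseline_points=working)

for k, f in fits.items():
    print(k, float(f.beta["median"].abs().median()))
print(predict_adjusted_dose(fits["reg_horseshoe"], "probe_sparse", "PM", DEFAULT_SCORES))
```

prints (seed 1; the analysis drivers print the same quantities for seed 20)

```
fixed 10.47
gaussian 8.25
horseshoe 3.91
reg_horseshoe 6.44
AdjustedDosePrediction(substance='probe_sparse', score=-2.0, phenotype='PM',
                       dose_pct=83.6, lower=35.7, upper=117.4)
```

Reading this: the fixed-effects fit gives the most extreme slopes and the
horseshoe variants the most conservative, with the Gaussian random effect
in between.  `probe_sparse` is a substance known from a single study of
n = 8 reporting a raw slope of 60; the fixed fit takes that at face value
(PM dose 100 − 2·60 ≈ −20% of label, nonsensical), while the regularized
horseshoe shrinks the slope from 60 to 8 and predicts a PM dose of ~84% of
label with an interval honestly spanning "maybe halve the dose, maybe do
nothing."  A
dense-evidence probe (8 studies, n = 300) gets nearly identical slopes
from all four regimes.

The numbered drivers under `analysis/` run the full story on seeded
synthetic datasets — generation (`01`), activity-score estimation and
pooling-bias quantification (`02`), study-property screening (`03`), the
four-regime comparison with forest plot (`04`), and the interval
calibration study (`05`) — writing tables under `results/`.  A `pgxdose`
CLI (`validate`, `simulate`, `activity-scores`, `screen`, `fit`, `compare`,
`run-all`) wraps the same library calls for shell use.

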