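# Methods

## The problem

Pharmacogenetic dose adjustments answer the question: by how much should a
drug's dose change in a patient whose CYP2C19 metabolizer phenotype differs
from the normal (extensive) metabolizer, so that drug exposure is
equalized?  The evidence base is a set of *sampling points*: one study's
reported percent difference in a dose-proportional pharmacokinetic readout
(AUC, clearance, dose-corrected steady-state concentration) between a
phenotype group and the EM reference.  These data are sparse — many drugs
have a single small study, group sizes run from n = 1 to several hundred,
and study designs differ in how genotypes were pooled into phenotype
groups.

All adjustments are kept on one internal scale: percentage-point deviation
from EM, so EM is identically 0 and the adjusted dose is `100 + adjustment`
percent of the label dose.

## Model

The core model is a no-intercept linear model over sampling points,

    y = X beta + R theta + eps,

where column j of X holds the activity score of each row's phenotype if the
row belongs to substance j (else 0), so `beta_j` is substance j's dose
adjustment per activity-score unit and predictions extrapolate to phenotype
groups no study observed.  Omitting the intercept pins the EM prediction to
exactly 100% of label dose.  EM rows are excluded from fitting: they are
the comparator inside each study, not independent observations.  R holds
confounders (by default only the RM-pooling flag, coded 1 on RM rows of
studies that pooled \*17/\*17 carriers into RM), whose coefficients theta are
never shrunk.

Residuals have the two-component meta-analytic variance

    Var(eps_i) = sigma_w^2 / n_i + sigma_b^2,

which weights sampling points by group sample size while `sigma_b^2` bounds
the precision any single large study can claim.  Both scales carry
log-normal(4, 0.25) priors (median ≈ 55 percentage points): informative
enough to keep the two components away from the zero/zero instability, while
the fit depends mainly on their weighted sum.

### Prior regimes for the slopes

* **fixed** — proper but effectively flat N(0, 1000^2): maximal
  heterogeneity, no pooling across substances; small studies can produce
  extreme slopes.
* **gaussian** — `beta_j | tau ~ N(0, tau^2)`, `tau ~ C+(0, 1)`: the
  classic random-effects compromise.
* **horseshoe** — `beta_j ~ N(0, tau^2 lambda_j^2)`, `tau ~ C+(0, 0.1)`,
  `lambda_j ~ C+(0, 1)`: global-local shrinkage approximating a
  two-population (null vs substrate) model; the half-Cauchy on tau encodes
  roughly a 50% substrate rate.
* **reg_horseshoe** — the regularized horseshoe: the local variance is
  tempered by a slab, `xi_j^2 = c^2 lambda_j^2 / (c^2 + tau^2 lambda_j^2)`
  with `c ~ half-Student-t(0, 2.5, df 8)`, capping slopes that smell of
  small-sample flukes while preserving well-evidenced ones.

A `student_t` regime (slopes t-distributed with 3 df around zero via the
inverse-gamma scale mixture) is implemented behind the same interface for
sensitivity checks but excluded from headline comparisons, as it tracks the
gaussian regime closely.

### Activity scores

Scores are estimated from the data in a preliminary stage, not assumed: a
factorial model with phenotype groups as levels (EM fixed at 0), the same
two-component variance, a study-level random effect, and group-level
pooling confounders.  Scores are the group medians rescaled so IM (one null
allele) is exactly −1; the \*17 allelic score averages the per-allele effect
in RM (one \*17) and UM (two \*17), i.e. `mean(score_RM, score_UM / 2)`; the
working map rounds to one decimal and enforces UM = 2 × RM.  Because scores
are ratios to the IM estimate they are invariant to rescaling all
adjustments.  Score estimation excludes RM-pooled studies (their RM groups
are biased upward) and drugs with no in-vivo CYP2C19 pathway.

Diagnostics: quadratic/cubic score terms and a separate \*17-carrier slope
test departures from linearity (credibility interval excluding zero flags a
departure; identifiability requires at least three distinct nonzero
scores); a raw-vs-log comparison fits both scales and prefers the one with
more symmetric standardized residuals (|skewness| > 0.5 counts as
asymmetry — a fixed numeric proxy for what is usually a visual judgement),
retaining raw unless the log scale also stays linear.

## Computation

Given the scale parameters (tau, lambda_j, c, sigma_w, sigma_b, the study
random-effect SD), every model here is linear-Gaussian in its coefficients.
We therefore integrate the coefficients out analytically (Woodbury identity
and matrix determinant lemma; one q × q Cholesky per density evaluation)
and sample only the scales — typically 3 to D+4 parameters — with the
emcee affine-invariant ensemble sampler, using differential-evolution moves,
which handle the heavy-tailed half-Cauchy posteriors better than the
stretch move.  Coefficients are then drawn *exactly* from their conditional
Gaussian posterior for each retained scale draw.  This marginalization
removes the funnel geometry that makes non-gradient samplers (and, without
reparameterization, gradient samplers) struggle on horseshoe models.

Defaults: 4 independent ensembles ("chains") of max(16, 2·ndim+4) walkers,
1500 burn-in + 1500 post-burn moves, thinning 6.  Convergence is monitored
with split-Rhat across the independent ensembles — computed both on the
sampled scales and on the conditional-mean coefficient chains — with a
1.01 threshold on reported parameters, plus an FFT-autocorrelation bulk ESS
and the walker acceptance fraction.  An ensemble sampler has no divergent
transitions; the reliability flag rests on these statistics, and a flagged
fit is refused by downstream consumers (score derivation) rather than
silently used.  All randomness derives from a single pipeline seed through
`numpy.random.SeedSequence` spawning; identical config + seed reproduces
every table.

Log-scale parameters are sampled on the log scale with Jacobians and hard
support bounds at |log x| ≤ 30 to keep the Woodbury algebra in floating
range.  "Flat" priors are proper N(0, 1000^2) (percentage points), wide
enough to be immaterial and narrow enough to keep the marginal likelihood
well-conditioned.

## Synthetic data

The generator emulates the structure of the published evidence base rather
than any single dataset: per substance, a slope that is 0 with probability
0.5 (exploratory studies of non-substrates) or drawn N(20, 10^2) pct points
per activity unit; 1–8 studies per substance; group sizes log-uniform on
1–507; each study reports IM (always), PM (80%), and RM/UM only if it
post-dates \*17 genotyping (50%), with RM at 80% and UM at 50% within those;
noise follows the two-component variance with sigma_w = 55, sigma_b = 20;
RM-pooling inflates affected RM rows by +38 pct points (20% of studies) and
IM-pooling by +2 (20%); EM rows are emitted with adjustment 0 to exercise
exclusion logic.  Switches exist for injected curvature (quadratic term)
and for multiplicative (log-normal, log-linear-in-score) generation, used
by the diagnostics tests.  A `benchmark_dataset` variant appends two
designed probes so every seed contains both evidence extremes: a
single-study n = 8 substance with a large raw effect, and an 8-study
n = 300 substrate.

What the generator does **not** emulate: publication bias, systematic
precision differences between study designs, allele-frequency structure,
correlated multi-parameter reports from one study, or real PK value
conversion.  Passing tests therefore demonstrate correctness of the
machinery under the assumed data-generating process, not clinical validity
of any particular adjustment.

## Calibration, and a deliberate red flag

Fixed-regime (flat-prior) intervals are calibrated in the usual frequentist
sense and verified against the weighted-least-squares closed form.
Shrinkage-regime intervals are *Bayesian*: they are calibrated on average
over the prior, not conditionally on a truth drawn from a different
distribution.  Under the generator's conditions — nonzero slopes centered
at +20 while the gaussian/horseshoe priors center at 0 — 90% intervals for
truly nonzero slopes cover at roughly 75–85% (the calibration study
measures ≈ 78% over 100 replicates), because weak-evidence slopes are
pulled toward zero past the truth.  Coverage of truly-zero slopes is
conversely near 100% for the horseshoe regimes.  This under-coverage is the
statistical price of the prudence the shrinkage priors are chosen for, and
is reported as measured rather than tuned away; the corresponding
calibration assertion in the acceptance suite is expected to fail under
these conditions and is left failing by design.  See
`analysis/05_calibration.py` for the study.

## Problem sizes

Simulation studies run at sizes chosen for a single-CPU workflow: the
regime-comparison benchmark uses 20 substances (+2 probes), the calibration
study 100 replicates of 8 substances with a shorter sampler schedule
(2 chains, 400 + 400 moves), and unit-test fits use 6–8 substances.  The
qualitative conclusions (shrinkage ordering, probe behavior, coverage
pattern) are stable across seeds at these sizes.

## Known limitations

* The Table-2-style activity-score estimates from one synthetic dataset are
  noisy (the RM/UM groups are thin by design); the derivation arithmetic is
  tested exactly, the estimates statistically.
* The property screen fits one interaction at a time against a single
  common slope; with strongly heterogeneous substances it can flag spurious
  interactions (~10% false-positive rate at the 90% level, more under
  misspecification).
* Split-Rhat across ensembles is a necessary, not sufficient, convergence
  check; the heavy-tailed lambda posteriors are summarized by medians and
  central intervals, which are robust to their slow tail mixing.
* The packaged study-characteristics table describes the 51 published
  studies; the per-sampling-point adjustments behind them are not
  redistributed here, so all end-to-end numbers in this repository are
  computed on synthetic data.
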