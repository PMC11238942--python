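# Methods note

This note records the statistical model, the conventions the implementation
commits to, and the numerical and design decisions a reader needs in order
to interpret or extend the results.

## Outcome model

For subject *i* at visit time *t* (years since baseline), the outcome
(MMSE, 0–30; optionally RAVLT immediate recall, 0–75) is modeled as

```
y_ij = x_ij' β + b0_i + b1_i · t_ij + e_ij
```

with a subject-level random intercept `b0_i` and random linear slope `b1_i`
drawn from an unstructured 2×2 covariance, and independent residuals
`e_ij ~ N(0, σ²)`. The fixed design contains:

- an intercept;
- a cubic polynomial in **centered time** `t' = t − 2.3` (terms `t1`, `t2`,
  `t3`);
- baseline covariate main effects (age, sex, baseline score, APOE ε4 allele
  count, CSF Aβ1–42, log CSF pTau, MRI volumes, and optional clinical
  covariates);
- covariate × `t'` interactions, i.e. covariate effects on the rate of
  decline.

### The centering convention

Interactions multiply *centered* time, the same `t' = t − 2.3` as the
polynomial. This is the single most consequential convention in the
package: with it, the shipped coefficient tables reproduce the published
worked-example prognoses (threshold-crossing times and 5-year predictions)
within the tolerance expected from 4-decimal coefficient rounding; with raw-
time interactions they do not. It also yields the useful exact identity
that the prediction at `t = 2.3` equals the covariate-weighted constant
part, which the acceptance suite checks with no tolerance. The random-
effect design, by contrast, uses **raw** time `(1, t)`, so `b0_i` is the
subject's deviation at baseline.

The shipped tables (`src/mmsetraj/data/coefficients_*_v1.json`) carry the
point estimates and standard errors of the final backward-selected models
for the MCI and mild-dementia groups, with `time_center = 2.3` and the
outcome bounds. Covariate coding: sex 0 = female / 1 = male; APOE ε4 as
allele count 0/1/2; pTau enters as its natural log (the engine accepts a raw
`ptau` value and applies the log itself, recording this in the patient's
audit trail); Aβ1–42 in pg/mL.

### Five-year prediction discrepancy

Evaluating the shipped MCI table for the median worked-example patient at
t = 5 gives 21.51, about 0.5 points above the published 21.0. The shipped
coefficients are rounded to 4 decimals and accumulate over covariate
products of magnitude up to ~900; the acceptance tolerance (±0.5 years /
±0.6 MMSE) is the budget for exactly this rounding. The threshold-crossing
examples land within ~0.3 years of the printed values, and the treated/
untreated ratios are exact.

## Synthetic cohort generator

No patient-level data are distributed; all fitting and evaluation run on a
synthetic generator that mirrors the published baseline summary statistics:

- MCI: age ~ N(66, 7²), 45.5% female, baseline MMSE ~ round(N(26.5, 2.3²)),
  APOE ε4 allele counts (0.224, 0.468, 0.308), Aβ1–42 ~ N(789, 217²),
  pTau ~ logN(3.391, 0.432²), total brain volume ~ N(1102, 113²) mL,
  hippocampal volume ~ N(7.0, 0.9²) mL; analogous values for mild dementia.
- Trajectories follow the shipped coefficient table (or any supplied table)
  plus bivariate-normal random effects and Gaussian residuals. Defaults:
  SD(b0) = 2.0, SD(b1) = 1.0, corr = −0.3, residual SD = 1.5 — chosen so
  that simulated between-patient 5-year percentile bands and out-of-sample
  R² land in the neighborhood of the published figures; the true values are
  unpublished, so these are calibration choices, not estimates.
- Visits are annual to 5 years with ±0.1-year jitter; dropout is a
  geometric per-interval hazard (default 0.15/year), missing completely at
  random by default with an optional outcome-dependent mode.
- Outcomes are rounded to integers and clipped to the instrument bounds.
  Rounding can be disabled (`round_outcomes=False`) for tests that need
  exact algebraic identities.
- Baseline covariates are blanked at configured rates (MRI volumes 26%,
  CSF 9% by default); age, sex and the baseline score are never missing.

Known limitations: covariates are drawn independently (no age–biomarker
correlation), dropout is not informative by default, and the residual model
is homoscedastic Gaussian, ignoring the floor/ceiling compression a bounded
integer scale produces. These simplifications bias simulated R² slightly
relative to a real cohort; the acceptance checks therefore use bands, not
point targets.

## Missing covariates: chained equations with PMM

Imputation is written in-package (no maintained Python MICE implementation
with predictive mean matching was available in the environment):

- per-variable models: Bayesian linear regression with a posterior
  coefficient draw, then predictive mean matching against the k = 5 nearest
  observed donors; binary variables use a logistic draw; ordered
  categorical variables (APOE count, BMI category, smoking) use PMM on an
  ordinal score — a pragmatic deviation from polytomous regression that
  keeps draws in the observed support;
- donor/predictor screen: pairwise-complete |correlation| ≥ 0.05, with the
  diagnosis group always retained;
- m = 25 completed data sets, 10 sweeps each, variables imputed in order of
  increasing missingness; convergence is flagged if chain means drift more
  than 5% over the last three sweeps;
- estimates are pooled with Rubin's rules: total variance
  `T = W + (1 + 1/m) B` with Barnard–Rubin small-sample degrees of freedom
  when a complete-data df is supplied, classical df otherwise.

## Model building

Candidate sets come in three nested tiers: demographics (age, sex, baseline
score), + CSF/MRI biomarkers, + clinical covariates; every candidate enters
as a main effect and a `× t'` interaction. Backward selection on each
completed data set removes the removable term with the largest Wald p above
α = 0.10 (ties break lexicographically), under two constraints: the time
polynomial, age and sex mains are forced, and a main effect may not leave
while its interaction remains. A refit that fails to converge keeps the
term under test and is flagged in the audit. Across the m sets, a term
enters the final model iff selected in at least half of them (so 13 of 25
keeps, 12 drops); hierarchy is repaired afterwards. The final structure is
refit on every set and pooled.

## Grouped ridge

As an alternative to selection, fixed effects can be shrunk by a grouped
ridge penalty solved as penalized GLS at the unpenalized REML variance
components. Four groups share penalties: the time polynomial, the baseline
score, remaining constant effects, and time-varying (interaction) effects;
the intercept is never penalized. Columns are standardized internally and
estimates returned on the original scale; λ = 0 reproduces the REML fixed
effects exactly (machine precision), and λ → ∞ drives a group's
standardized coefficients to zero. Penalties are tuned by subject-level
5-fold cross-validated squared error inside the training data: a shared
penalty on a log grid first, then one refinement pass per group.

## Evaluation

Internal validation is subject-level k-fold cross-validation (subjects, not
observations, are partitioned; the per-fold assignment is a seeded
permutation). Held-out subjects are predicted from fixed effects only,
since their random effects are unknowable without using their outcomes.
Metrics: RMSE, median absolute error, and out-of-sample
R² = 1 − SSE/SST with SST around the held-out mean (negative values
possible). External validation applies a frozen table with no refitting.

## Prediction engine

- Threshold crossings: the first crossing of the fixed-effect trajectory is
  bracketed on a 0.02-year grid over the horizon (default 20 years) and
  refined by Brent root finding to 1e-4 years; "never within horizon" is
  reported as infinity.
- Treatments: a fractional decline reduction r is modeled by default as
  **time dilation**, `treated(t) = natural((1 − r)·t)` — under which the
  treated crossing time is exactly `untreated / (1 − r)`, matching the
  published treated prognoses — or alternatively as **decline scaling**,
  `treated(t) = y(0) − (1 − r)(y(0) − natural(t))`. Both agree for linear
  decline; effects are assumed constant over time.
- Uncertainty display: individual percentile bands simulate n = 1000
  random-effect draws around the patient's mean curve (residual noise
  excluded by default, as the band depicts stable between-person
  variation); population fans take empirical percentiles of per-subject
  BLUP-adjusted predictions, omitting values outside the instrument bounds.
- Predictions are reported unclipped with out-of-bounds and extrapolation
  flags (the data range is ~5 years).

## Reproducibility and numerics

- REML fitting uses `statsmodels.MixedLM` with a fixed optimizer cascade
  (L-BFGS → BFGS → Powell), so refits are deterministic; rank-deficient
  designs are rejected with the offending columns named via pivoted QR.
- All randomness flows from one master seed through named substreams
  (`simulate`, `imputation`, `folds`, …) hashed with CRC32, so each stage
  is independently reproducible and artifacts embed the seed plus a
  configuration hash.
- Stochastic tests in the acceptance suite use simulation sizes chosen to
  keep the full suite within a CI-friendly budget (e.g. 20 replications of
  500 × 5-visit cohorts for parameter recovery, 200 replications of
  120-subject cohorts for selection operating characteristics); the
  statistical bands were fixed before the tests were first run, and are
  wide enough for these sizes (binomial/Monte-Carlo error accounted for).
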