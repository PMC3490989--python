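# Methods

This note documents the statistical content of `growthineq`: the models and
procedures implemented, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and known limitations.

## Z-scores and classification

Measurements are converted to z-scores with the LMS method: a reference
distribution at each age (or length) is summarised by a Box-Cox power `L`, a
median `M` and a coefficient of variation `S`, and

    z = ((x/M)^L − 1) / (L·S)   for L ≠ 0,
    z = ln(x/M) / S             for L = 0.

The implementation switches to the log branch for `|L| < 1e-12` and is
continuous there (verified to 1e-6 over a grid). Reference parameters at
off-grid ages are linearly interpolated in days (or cm for
weight-for-length/height); there is **no extrapolation** — an index value
outside the grid yields a missing z-score.

Two deliberate divergences from the WHO software conventions:

* the **restricted transform** that some growth-standard software applies to
  weight-based indicators beyond ±3 SD is not implemented; plain LMS is used
  everywhere. This changes extreme weight-based z-scores slightly but no
  classifications at the ±2 cut-offs.
* no recumbent-vs-standing length correction is applied; cohorts that measure
  recumbent length up to ~24 months and standing height later match the
  reference's own convention, so a correction would double-count.

Classification uses strict inequalities: stunting/underweight/wasting are
`z < −2` on haz/waz/whz, overweight is `bmiz > 2`; a z of exactly ±2 is
negative. Implausible values (haz outside ±6; waz outside [−6, 5]; whz and
bmiz outside ±5 — standard data-cleaning limits, configurable) are flagged and
excluded from both numerators and denominators.

## Midpoint ranks and quantile assignment

Subjects are ordered by income; group boundaries fall at (weighted) cumulative
shares j/k. Tied values are never split across a boundary: a tied block is
assigned as a unit to the group in which its inclusive cumulative share lands.
This makes the assignment order-independent and reproducible; heavy ties
produce unequal groups. Group shares f_i are computed from realized sizes and
midpoint ranks are r_i = Σ_{j<i} f_j + f_i/2, so non-nominal shares propagate
into the ranks. A `nominal=True` flag fixes ranks at (i−0.5)/k for reproducing
worked examples computed at the textbook midpoints. `k = 1` is allowed (one
group at rank 0.5), since degenerate inputs otherwise have no representation.

## SII

Two estimators, selectable per run:

* **grouped** (default): weighted least squares of group prevalence on midpoint
  rank, weighted by group size. This is the classical description of the index
  and is exactly what the published tables permit recomputing. With two groups
  the slope is reported and the CI marked unavailable (no residual degrees of
  freedom).
* **individual**: linear-probability regression of the subject-level outcome on
  the subject's group midpoint rank with heteroskedasticity-robust (HC1)
  standard errors; with equal weights its point estimate coincides with the
  grouped estimator on collapsed data (verified to 1e-10). Its standard errors
  reflect individual-level information and are the ones used for
  CI-coverage validation.

The SII is reported in percentage points; by construction it equals the fitted
prevalence at rank 1 minus the fitted prevalence at rank 0 (asserted
algebraically on every fit). CIs are estimate ± 1.96·SE.

## RII

Maximum-likelihood binomial logistic regression of the outcome on midpoint
rank; RII = exp(slope), CI = exp(slope ± 1.96·SE). Grouped (counts per group,
possibly non-integer when reconstructed from printed percentages) and
individual inputs give identical point estimates; sampling weights enter as
frequency weights in the likelihood. The fit uses iteratively reweighted least
squares (tolerance 1e-10, at most 100 iterations); a non-finite or runaway
slope (|β| > 50) raises a convergence error with a diagnostic, as does an
outcome with no variation.

## Design weighting

An oversampling design is a partition of children into strata with inclusion
probabilities π; selection is at the child level and retained children carry
weight 1/π into every estimator (prevalence, quantile boundaries, SII, RII,
test tables). Prevalence CIs are Wilson intervals computed on the effective
sample size (Σw)²/Σw², the standard design-based adjustment. Cross-cohort χ²
tables use effective counts Σw·y and Σw·(1−y); weighting a χ² table is
non-standard, and this effective-count convention is the package's documented
choice.

## Cross-cohort tests

* Pearson χ² on 2×k tables (no continuity correction), df = k−1.
* Cochran–Armitage linear trend with strictly monotone scores (cohort years),
  df = 1; equals the 2×2 Pearson statistic at k = 2 and is invariant to affine
  score changes.
* Heterogeneity of SII/RII across cohorts: Cochran-Q on the coefficients
  (linear scale for SII, log-odds for RII) with inverse-variance weights,
  df = count − 1. The published analysis names no specific heterogeneity test;
  Cochran-Q is the standard fixed-effect choice.
* Linear trend in the coefficients: fixed-effect meta-regression of the
  coefficients on cohort year; squared Wald statistic on 1 df.
* Summary arithmetic: percent change 100·(p_to − p_from)/p_from and prevalence
  ratios, rounded only at presentation (prevalence and SII to 1 decimal, RII to
  2, mirroring the published tables).
* Sample skewness uses the population-moment convention m₃/m₂^{3/2} with no
  small-sample correction; published skewness values computed from raw data are
  not reproducible from summary tables and are not validation targets.

All p-values are two-sided; under the null the χ² and trend p-values are
checked for uniformity by simulation (KS test at α = 0.001, 2,000 replicates).

## Synthetic cohorts

The generator's purpose is parameter-recovery testing: it draws data whose
true inequality indices are known.

* **Income** is log-normal (default log-mean 6.0, log-sd 0.8 — an illustrative
  right-skewed distribution; real income-distribution shape varies). Continuity
  makes ties impossible; tie handling is exercised by separate hand-built
  fixtures.
* **Risk gradients** are linear in the relative income rank r (the empirical
  quantile of the child's income): P(stunting) = a + b·r and similarly for
  overweight. Defaults a = 0.28, b = −0.28 (stunting) and a = 0.07, b = 0.08
  (overweight) echo the steep early-80s stunting gradient and the shallower
  positive overweight gradient of a middle-income population.
* **Latent z-scores** are normal within rank: the mean is shifted to
  −2 − Φ⁻¹(p(r))·sd so that P(z < −2) = p(r) exactly (mirrored for the
  overweight tail above +2); sd defaults to 1 z-score unit. Raw length and BMI
  are obtained by inverse-LMS against the supplied reference and weight is
  BMI·(length/100)², so the z-score engine recovers the latent values to
  better than 1e-9 (round-trip property).
* **Birthweight** is the birth-visit weight in grams (10 g precision),
  computed for every child whether or not a birth row is requested — the two
  fields can never disagree. A child-level frailty shared across visits
  (correlation 0.5 between the birth-size noise and each visit's z-noise)
  gives low birthweight a realistic association with later stunting (odds
  ratio ≈ 2.5 in the default configuration), which is what makes unweighted
  estimation on the oversampled design visibly biased.
* **The bundled reference is synthetic**: smooth plausible L/M/S curves
  (length L = 1; BMI L declining through zero with age, which also exercises
  the log-branch region). Birth S values are larger than later ones so that
  the birthweight coefficient of variation is ~17% and the low-birthweight
  (< 2500 g) share lands near 7% — the scale at which an "all low-birthweight
  children plus 20% of the rest" design is meaningful. Real growth-standard
  tables in the same CSV schema (`indicator,sex,index_value,L,M,S`) are a
  drop-in replacement.
* **Attrition** drops each follow-up row independently (default 8% per visit,
  matching follow-up rates in the low-90s%); the birth examination is always
  present. Visits are generated independently given rank and frailty — there
  is no within-child growth-trajectory model, so the generator cannot be used
  to study longitudinal tracking, catch-up growth, or age-by-income
  interactions. Stunting and overweight latents are independent given rank.

Consequently, passing parameter-recovery tests shows the estimators are
consistent and their CIs honest **under this generative model** — linear
gradients, normal latents, non-informative attrition — not that real cohort
data meet those assumptions.

## Pipeline conventions

* Visit windows (months): birth [0, 1), 1y [9, 18), 2y [18, 30), 4y [42, 60);
  configurable, wide because real "two-year" rounds can average 19–24 months.
  The published cohorts' exact windows are not stated; these are declared
  defaults, not inferred ones.
* Quintiles and indices are computed per cohort × visit on the records with a
  usable indicator and non-missing income; overall prevalence uses all records
  with a usable indicator.
* Malformed CSV rows (non-positive measurements, negative weights, unknown
  sex, duplicate child-visit keys) are collected into an error report and
  dropped, never silently; a missing required column is a schema error naming
  the column.
* A visit absent from a cohort yields unavailable cells (`(-)` in the rendered
  report), not an abort, and cross-cohort tests use the available cohorts.
* Outputs carry full precision; rounding happens only in the rendered report.
  Run logs contain no timestamps, so identical inputs give byte-identical
  output trees (verified in the tests).

## Problem sizes used in validation

Single-shot parameter recovery uses one cohort of 50,000 children (Monte-Carlo
SE on the SII ≈ 0.9 points); CI-coverage uses 200 replicate cohorts of 5,000;
design-weighting checks use 20,000 children; the end-to-end determinism run
uses three cohorts of 5,000 across all four visits. These sizes put
Monte-Carlo noise well below the tested tolerances while keeping the whole
suite fast.

## Known limitations

* No IOTF cut-offs, head circumference, MUAC, concentration index or Gini;
  no multilevel or covariate-adjusted models.
* The grouped SII's model-based SE treats group prevalences as homoskedastic
  up to size weights; with five groups and three residual degrees of freedom
  it is noisy. Use the individual estimator when subject-level data exist.
* Wilson intervals with effective sample size are approximate under strongly
  variable weights.
* Published cohort-level prevalences cannot be reproduced without the original
  individual-level data; the bundled published tables support derived
  arithmetic (percent changes, ratios, grouped re-fits) only.
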