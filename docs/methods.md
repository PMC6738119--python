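# Methods

This note documents the models, conventions and design choices behind
`invigor`, in the order the pipeline runs them.

## Volumes from paired mammogram dimensions

A lesion is represented by two diameters in mm; the reader enforces
`dim_major >= dim_minor` (swapping with a warning if violated). The
greater dimension is interpreted as the lesion "height", i.e. the
diameter of the semi-major axis. Three shape assumptions are supported:

| shape           | formula                                | convention |
|-----------------|----------------------------------------|------------|
| sphere          | V = (π/6)·d̄³                           | d̄ = mean of the two diameters (default) |
| cylinder        | V = π·(minor/2)²·major                 | height = greater dimension |
| oblate spheroid | V = (4/3)·π·(major/2)²·(minor/2)       | equatorial semi-axis used twice |

How a sphere should collapse two unequal diameters into one is
genuinely open; the arithmetic mean is the most common mammographic
convention and is the default, with `major`, `minor` and
`geometric_mean` selectable (`sphere_rule`) for sensitivity analysis.
Prolate or tri-axial ellipsoids are deliberately out of scope.

## Growth laws and rate inversion

Each law is the closed-form solution of a one-parameter ODE in volume:

* exponential: V(t) = V₀·e^{rt}
* power law:   V(t) = (V₀^{1−α} + (1−α)·r·t)^{1/(1−α)}, α ∈ (0, 1),
  defaults α ∈ {1/2, 2/3}
* Gompertz:    V(t) = K·(V₀/K)^{exp(−rt)}

A patient's rate is the exact algebraic inverse given
(V₀ at screening, V₁ at diagnosis, Δt days); `forward_volume` and
`invert_rate` round-trip to 10⁻⁹ relative error (verified by property
test). Numerical caveat: for the saturating Gompertz law, r·t large
enough that V₁ is within machine precision of K makes inversion
ill-conditioned; realistic Gompertz rates are small relative rates
(per-day log-volume scale) and the tests draw them on that scale.

Conventions:

* **Units.** Power-law rates formally carry mm^{3(1−α)}/day; the field
  labels all rates "mm³/day". The numeric value is stored exactly as
  the closed form yields it and a `rate_unit` descriptor travels with
  every result; the conventional label is kept for comparability.
* **Carrying capacity.** K defaults to 10⁶ mm³ (≈10¹² cells at 10⁹
  cells/cm³, the conventional lethal-burden bound) and is configurable;
  volumes at or above K make that record invalid for Gompertz (flagged,
  never silently dropped).
* **Negative rates** (diagnostic volume below screening volume) are
  retained and flagged as shrinkage; they participate in cutpoint
  search.
* **Months → days** at 30.44 days/month wherever an interval is given
  in months.
* **Back-dating.** `tumour_age` solves the forward law for t. The power
  law admits inception volume 0 (finite age from zero); exponential and
  Gompertz growth never leave zero volume, so a positive inception
  volume is required there.

## Survival primitives

Death from breast cancer is the event; everything else is censored.
Kaplan–Meier and the two-group log-rank test are implemented natively —
the cutpoint stage evaluates the log-rank statistic at hundreds of
candidate thresholds, and `logrank_scan` vectorises the risk-set
bookkeeping over all thresholds in one pass — and both are
cross-checked against lifelines in the test suite. Cox
proportional-hazards fitting delegates to lifelines with Efron tie
handling (the common default); AIC is reported as 2k − 2·ln L with k
the number of covariates; p-values are two-sided Wald. The 10-year BCSS
horizon is implemented as administrative censoring at 120 months
(boundary inclusive) applied before univariate ranking; multivariate
validation fits use full follow-up unless a horizon is requested.

## SM-INVIGOR: grid ranking and cutpoint optimisation

`rank_models` evaluates 3 shapes × 4 laws × 2 forms = 24 entries. For
each combination the per-patient rates are computed, then a univariate
Cox fit of the continuous rate and of its dichotomisation at the
log-rank-optimal cutpoint are ranked by AIC (each k = 1). Two
conventions matter:

* **Common subset.** AIC values are comparable only across fits of the
  same subjects, so all non-failed combinations are fitted on the
  subset of patients with valid rates under *every* usable combination.
  A combination with more than 10% invalid rates is marked failed and
  excluded from ranking.
* **Cutpoint admissibility.** Candidate thresholds are midpoints
  between consecutive distinct sorted rates with at least 10% of
  patients on each side (preventing degenerate optima); exact ties in
  the maximised χ² break to the smaller threshold, making the stage
  fully deterministic. "Fast" means rate strictly greater than the
  threshold.
* **Maximal selection.** The p-value at the optimised cutpoint is
  reported raw, matching common practice for this index; it is
  optimistic under maximal selection, and
  `permutation_adjusted_p` (B = 1000 by default) is provided as a
  clearly-labelled extension. An optional k-fold cross-validated
  partial-likelihood criterion is likewise available behind a flag
  rather than as the primary ranking, which uses plain AIC.

The screening and diagnostic volumes themselves are also fitted as
continuous univariate Cox covariates and reported alongside the grid,
to contrast change-based indices with single-time-point volume.

## Surr-INVIGOR: the KNN surrogate

Candidate features default to Ki67 (%), mitotic score, histological
tumour size (mm), NPI, grade, nodal stage and the mammographic
diagnostic size (mean of the two diagnostic diameters — the natural
reading of a second "tumour size" variable alongside the histological
one; configurable). Screening uses Welch's unequal-variance two-tailed
t-test per feature (robust to the unequal group variances seen in
practice); features with p < 0.2 are admitted, ranked by ascending p.
Features with zero variance in both groups are excluded with a
diagnostic.

Sequential selection grows feature sets as prefixes of the screening
ranking. At each set size, each algorithm in the zoo receives a seeded,
budgeted hyperparameter search — exhaustive over odd
k ∈ {1, 3, …, min(31, n/3)} for KNN; random draws for the optional
scikit-learn comparators (svm, decision tree, naive Bayes, linear
discriminant, random forest) — capped at `budget` scored
configurations (default 180). Every configuration is scored by
stratified 5-fold cross-validation repeated `repeats` times
(default 10; raising it to ~100 sharpens the selection at
proportionally higher cost), with standardisation fitted on each
training fold only and accuracy defined as plain concordance with the
growth-index label. The winner maximises mean CV accuracy; ties break
to fewer features, then zoo order, then smaller k — parsimony wins at
equal skill.

The frozen artifact is always the best KNN configuration (KNN is the
prediction path; comparators are recorded in the trace and never gate
the pipeline): selected features, full-training standardisation
parameters, standardised training points, k, CV and resubstitution
accuracy, and the seed ledger, serialised as versioned JSON that
reloads bit-identically. Prediction standardises the query with the
*stored* parameters, uses Euclidean distance, breaks distance ties by
training-point order (stable sort) and cannot tie votes because k is
odd. Missing feature values are handled complete-case per fitted
feature set.

## Synthetic cohorts

The generator emulates the statistical structure of a
missed-cancer serial-mammography cohort:

* **Screening volume**: log-normal, moment-matched to mean 2742 mm³ and
  SD 7619 mm³ (at n ≈ 92 the implied range is of order 20–90,000 mm³,
  bracketing the reference 53–56,115 mm³).
* **Interval**: scaled Beta on [4, 37] months solved for mean 18 and
  mode 17.5. (A triangular distribution with that mode was considered
  and rejected: on [4, 37] its mean is 19.5, inconsistent with the
  mean-18/median-17.5 calibration that the Beta satisfies
  simultaneously with the range.)
* **True rate**: half-normal with mean 0.08 (conventional mm³/day
  units), truncated at zero; mass above 0.53 is < 10⁻⁶.
* **Diagnostic volume**: forward simulation of the true law (default
  power α = 1/2) — so pipeline-inverted rates reproduce the generator's
  truth exactly, a property the tests assert to 10⁻⁶.
* **Dimensions**: back-computed from each volume with an aspect ratio
  drawn uniformly on [1, 2] per measurement, so the geometry stage is
  exercised non-trivially and wrong-shape volumes acquire realistic
  distortion.
* **Survival**: step hazard on the true group (rate > 0.045), with
  exponential baselines set by 10-year BCSS of 92% (slow) and 72%
  (fast) — a fast:slow hazard ratio of ≈3.9 — and uniform
  administrative censoring on [60, 180] months. This yields roughly 75
  events per 400 patients.
* **Features**: drawn conditionally on the group (Ki67 normal with
  fast/slow means 24/11; ordinal mitotic score, grade and nodal stage
  with group-shifted probabilities; log-normal histological size; NPI
  computed from its formula 0.2·size_cm + grade + nodal stage; the
  remaining features near-uninformative marginals). Conditional
  independence given the group is a modelling choice: no joint
  volume–feature distribution is available to calibrate against.

The ground-truth sidecar (true rate, group, volumes, latent event and
censoring times) is returned, and written, separately from the cohort
table; pipeline stages never read it.

What the generator does *not* emulate: mammographic measurement error,
radiologist recall behaviour, correlated feature noise within groups,
non-proportional hazards, or competing risks. Passing tests therefore
demonstrate internal correctness and statistical behaviour under the
assumed data-generating process, not performance on real cohorts.

## Statistical power of model-grid recovery

The rate indices of different laws (and of different shapes, after the
aspect-ratio distortion) are 94–99% rank-concordant on generated
cohorts, so distinguishing the generating combination by AIC hinges on
a few discordantly-classified patients. With ~75 events per cohort of
400 the AIC gaps between the true combination and its nearest
neighbours (power α = 2/3; oblate spheroid) are typically 0–5 units,
within maximal-selection noise: the generating combination wins the
grid in roughly 40% of cohorts at n = 400, rising to ≈95% at n = 800
and ≈100% at n = 1600 (the procedure is consistent, and the regular
test suite asserts the trend). The recovered *cutpoint* is far more
stable: its median across seeds sits near the generative 0.045 already
at n = 400.

## Problem sizes and defaults

The test suite and acceptance script run on synthetic cohorts of
n = 92–400 (10,000 for calibration moments, 1241 for the validation
illustration), 20–50 seeds per Monte-Carlo claim, CV repeats of 10 and
a selection budget of 180 — sizes chosen so the full pipeline and its
checks execute in minutes on one CPU while keeping the Monte-Carlo
standard errors well inside the asserted margins.

## Known limitations

* The growth index needs two informative mammograms; cohorts where the
  screening lesion is genuinely absent (true interval cancers) are out
  of scope, as is any image processing — the package consumes measured
  dimensions.
* The raw maximally-selected log-rank p is anti-conservative; use the
  permutation adjustment when the cutpoint itself is in question.
* AIC differences of a few units between near-duplicate rate indices
  are not meaningful at small event counts (see the power section
  above); report the grid, not only the winner.
* KNN surrogate accuracy is measured as concordance with the growth
  index, which is itself an estimate; survival separation in an
  independent cohort is the more meaningful validation and is what
  `apply_surrogate` reports.
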