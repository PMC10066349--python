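# Methods

## Scoring choice blocks

Each block holds nine binary decisions at one social distance `N`: keep a
selfish amount `a ∈ {155, 145, …, 75}` dollars, or keep 75 and give 75 to
person `N`. Scoring fits `P(share) = logistic(b0 + b1·a)` and reports the
indifference point `−b0/b1`, the amount at which the respondent is
indifferent. Four regimes are distinguished:

* **all keep** → the point is assumed at \$70 (just below the smallest
  amount);
* **all share** → assumed at \$160 (just above the largest);
* **perfect separation** (all shares strictly below all keeps on the
  amount ladder, or the reverse) → the logistic MLE diverges while
  `−b0/b1` converges to the midpoint of the two amounts bracketing the
  switch, so that midpoint is returned analytically. This equals the
  vanishing-ridge limit of a penalised logistic fit, which the tests
  verify against scikit-learn;
* **otherwise** → Newton–Raphson logistic MLE; the point is clamped to
  [70, 160] for parity with the assumed endpoints. A degenerate fit — no
  slope, or a fitted slope implying share probability *rising* with the
  selfish amount — falls back to the midpoint of the mean kept and mean
  shared amounts and is flagged.

The amount willing to forgo is `v = point − 75`, hence `v ∈ [−5, 85]`;
negative values are retained (not floored) throughout, because the
all-keep endpoint deliberately implies a small negative forgone amount.
Monotonicity caveat: on monotone single-switch response patterns the
estimator is exactly monotone in the switch point (midpoint rule), but
the logistic MLE is *not* globally monotone under arbitrary response
flips on multi-switch patterns; the property tests are scoped
accordingly.

Participants switching between keeping and sharing more than twice within
any block are flagged inconsistent and excluded from discounting analyses
("more than two" is strict: exactly two switches is retained). Switches
are counted on the descending amount ladder regardless of presentation
order.

**AUC.** The model-agnostic summary normalises distance by the maximum
distance (100) and `v` by the maximum possible forgone amount (\$85),
then sums trapezoids over the observed points, spanning x = 0.01 to 1.
A flat maximal curve therefore scores 0.99, not 1.0. Normalising by the
participant's own maximum `v` is available as an option but is undefined
when that maximum is not positive, which is why maximum-possible is the
default.

**Single-curve hyperbolic fits.** `v(N) = v0 / (1 + exp(logk)(N−1))` is
fitted by least squares, profiling `v0` (conditionally linear given
`logk`) and minimising over `logk` on a 121-point grid over the search
box [−10, 5] followed by bounded scalar refinement. Flat or increasing
curves push `logk` to the lower bound and are flagged non-identifiable.
The rate is estimated on the log scale because raw `k` is heavily skewed
near zero.

## Hierarchical hyperbolic model

Level 1 models each participant's seven forgone amounts as a hyperbola in
centered distance `N − 1` (so `v0` is the value for the closest person)
plus Gaussian residual. Level 2 gives every participant random `v0` and
random `logk`; the `logk` mean is a linear function of altruist-group
indicators (control baseline), age (uncentered, in years), sex coded
Female = 1, and optionally education/income indicators, a trait such as
honesty-humility, and its group interactions.

Estimation maximises the marginal likelihood, integrating the bivariate
random effect out with a Laplace approximation around each participant's
conditional mode. Modes are found by a damped, fully vectorised Newton
iteration; the curvature uses the Gauss–Newton approximation to the
conditional Hessian, standard for nonlinear mixed models and exact at an
interpolating mode. Adaptive Gauss–Hermite quadrature of any order is
available (`method="agh"`); order 1 reproduces the Laplace value exactly,
and estimates move by less than 1e−3 beyond order 5 on test fixtures.
The random-effect covariance is unstructured by default (log-Cholesky
parameterisation; diagonal available), the residual variance enters as
`log σ`, and the `logk` intercept is box-constrained to [−10, 5] purely
to keep `exp(logk)·N` finite. Starting values come from two-stage
per-participant curve fits (means, OLS of `logk` on the level-2 design,
moment estimates of the covariance), which avoids the flat region of the
hyperbolic likelihood. The outer optimiser is L-BFGS-B with numerical
gradients; a non-converged fit is returned flagged, never silently.

Inference: standard errors from the inverse of the central-difference
observed-information matrix; two-tailed p-values against a t reference
with (participants − level-2 parameters) degrees of freedom (a normal
reference is available via `df_method="z"` — the exact small-sample
reference for this model is not settled, and the choice matters little at
n ≈ 275). Group-level predicted curves plug fixed effects into the
hyperbola at covariate means, with delta-method confidence ribbons.

With `random_effects=False` both variances are pinned to zero and the
model reduces exactly to pooled nonlinear least squares, verified against
an independent `scipy.optimize.least_squares` oracle at 1e−4.

## Cohort statistics

Trait comparisons are indicator-coded OLS with age and sex (optionally
education and income) as covariates; no multiple-testing correction is
applied by default across the trait battery, mirroring simultaneous
multivariate comparison, though Benjamini–Hochberg adjustment is
provided. Demographic balance uses Pearson chi-square *without*
continuity correction — required to reproduce the published 0.85 (sex)
and 16.22 (education) statistics from counts reconstructed from printed
percentages — and pooled-variance t tests from summary statistics.
Cognitive-reflection scores are dichotomised at 2-of-3 correct.

**Matched bootstrap.** To compare a rare cohort against a reference
population that differs demographically (the reference skews much
younger), B = 5000 samples of size m = 50 are drawn without replacement,
each matched to the target cohort's joint age-quantile × sex composition
(quartiles of the target's own age distribution by default; the
outermost bins absorb out-of-range population ages; largest-remainder
rounding keeps each sample at exactly m). The one-sided p is the
proportion of bootstrap means exceeding the comparison mean — its
resolution is 1/B — and a doubled-tail two-sided p is also reported.
The small fixed m is deliberately conservative given the population age
skew. Joint (rather than marginal) composition matching is used.

**Rating models.** Third-person trait ratings are modelled with a
random-intercept-per-rater linear mixed model (ML, via statsmodels
MixedLM), contrasting every target against the "average person"
baseline; a single-rater table degrades to OLS with a warning.

## Classification

25 standardised predictors (discounting rate `logk` from the mixed model,
six personality dimensions, four empathy subscales, five risk-taking and
five risk-perception subscales, three psychopathy subscales, and the
dichotomised reflection score) feed an L1-penalised logistic classifier.
The data are split 80/20 stratified by label; standardisation uses
training statistics only. The penalty grid holds 100 log-spaced values
from λ_max (the smallest penalty with an all-zero solution, computed in
closed form) down four decades; 5-fold class-stratified cross-validation
scores each λ by mean binomial deviance (misclassification optional),
and the selected penalty is the largest whose CV loss is within one
standard error of the minimum — the simplest qualifying model. The
solver is liblinear with a large intercept-scaling factor so the
intercept is effectively unpenalised. Held-out performance is the
rank-based AUROC with midrank ties, algebraically the scaled
Mann–Whitney U. A follow-up unpenalised logistic model reports odds
ratios with Wald intervals for the selected features plus age, sex,
education and income on complete cases; perfect separation triggers a
flagged, lightly penalised refit.

## Representational similarity

For six groups × six traits, each cell is the group mean divided by its
standard error, z-scored across groups within trait (population ddof = 0
convention; ddof = 1 available). Pairwise absolute differences among the
36 cells give a symmetric, zero-diagonal 36×36 dissimilarity matrix with
630 unique lower-triangle pairs. Two matrices are compared by Spearman
rank correlation of their lower triangles. Significance uses a Mantel
permutation test that reassigns the six *group identities*, moving each
group's block of trait cells jointly over rows and columns — only 720
distinct relabelings exist, so they are enumerated exactly whenever the
requested permutation count allows, which strictly dominates sampling;
a sampled mode and a free 36-cell permutation scheme are retained. The
p-value counts permuted statistics ≥ the observed one, including the
identity in the exact case, so p ≥ 1/720.

## Synthetic data

The generator produces every table the pipeline consumes, from one root
seed via named substreams (cohort / choices / population / beliefs), so
each table regenerates independently and byte-identically.

* **Cohort**: seven groups at the published sample sizes (a
  `choice_sample` variant mirrors the discounting-task analytic sample);
  group trait effects are standardised mean shifts, by default +0.5 SD
  honesty-humility and −0.5 SD personal distress in all altruist groups;
  ages ≈ 44 ± 12.5 (altruists) vs 38 ± 9 (controls), consistent with the
  published demographics.
* **Discounting parameters**: `v0` truncated-normal (78, 8) on [0, 85] —
  the range observable from the task ladder; `logk` normal with control
  mean −2.8 and group shifts matching the fitted group coefficients
  (−0.63 to −1.93), SD 1.5.
* **Choices**: the generative model inverts the scoring model —
  `P(share) = logistic((v*(N) − (a − 75))/τ)` with temperature τ in
  dollars. τ is a free calibration knob (within-participant choice noise
  is not identifiable from published results); the default τ = 2.5 was
  set once so the simulated inconsistency-exclusion rate (~5–6%) matches
  the observed study exclusion rate (16 of 291).
* **Reference population**: 50,000 rows by default (a desk-scale stand-in
  for the ~350k-person reference survey), age ≈ 28 ± 10 — markedly
  younger than the cohort — with country and sex labels and trait scores
  without group structure.
* **Belief sliders**: per rater × target, seven sliders in [0, 100] from
  a hyperbola with target-specific `logk` (altruist targets −3.0 vs
  −1.5 for the average person) plus rater-level generosity and belief
  heterogeneity and slider noise, clipped to the scale.

What the generator deliberately does **not** emulate: the real trait
covariance structure across scales (traits are independent given group),
item-level questionnaire responses, non-normal trait distributions, and
any dependence between traits and discounting beyond group membership.
Passing tests therefore demonstrate that the estimators recover the
structure they assume, at realistic sizes and noise levels — not that
real cohorts satisfy those assumptions.

## Numerical choices and limitations

* Scoring endpoint clamps, the [70, 160] clamp on logistic estimates, and
  the degenerate-slope fallback are discontinuous by construction;
  downstream models treat the scored `v` as data.
* The Laplace approximation is accurate here because each participant
  contributes seven observations to two random effects; adaptive
  quadrature is available when curvature is in doubt.
* The marginal-likelihood Hessian is computed by finite differences; on
  near-singular information (e.g. a variance estimated at zero) standard
  errors are reported as missing rather than fabricated.
* Bootstrap p-values have resolution 1/B and are not corrected across
  traits.
* Problem sizes in the test suite are chosen at desk scale: recovery
  checks run 10–20 replicates of cohorts of 200–275 participants, the
  null-calibration check uses 60 replicates of 60-participant fits, and
  the bootstrap calibration uses a 40,000-row population; these sizes
  keep Monte-Carlo error well inside the asserted tolerances.
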