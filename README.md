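# altrudisc

Social-discounting and trait analysis for cohorts of rare real-world
altruists — living organ and marrow donors, heroic rescuers, humanitarian
aid workers — compared against community controls. The package implements
the full analysis chain for studies asking *what distinguishes people who
make large real sacrifices for strangers*: scoring of binary keep/share
choices, hierarchical hyperbolic discounting models, matched-bootstrap
trait comparisons, penalised classification, and representational
similarity between perceived and actual group traits. Because raw data
from such cohorts are typically protected, a first-class synthetic-data
generator reproduces the statistical structure the analyses assume, so
every stage runs and is testable end to end without any download.

## The model

In a social-discounting task a respondent imagines the 100 people closest
to them and, for each social distance `N ∈ {1, 2, 5, 10, 20, 50, 100}`,
makes nine binary choices between keeping a selfish amount (`$155` down to
`$75` in `$10` steps) or keeping `$75` and giving `$75` to person `N`.
A logistic fit of choice on amount yields the indifference point
(`−b0/b1`, the amount at which keeping and sharing are equally likely);
all-keep blocks are assigned `$70` and all-share blocks `$160`. The amount
willing to forgo is `v = indifference − 75 ∈ [−5, 85]`.

Across distances, `v` declines hyperbolically. The core model is a
nonlinear mixed-effects model, fitted by maximum marginal likelihood with
a Laplace approximation (adaptive Gauss–Hermite optional):

    level 1:  v_Ni = v0_i / (1 + exp(logk_i)·(N−1)) + e_Ni
    level 2:  v0_i   = β00 + r0_i
              logk_i = β10 + Σ_g β1g·Group_gi + β_age·Age_i + β_sex·Sex_i + r1_i

with `(r0_i, r1_i)` bivariate normal. `logk` is the log discounting rate:
more negative means shallower discounting, i.e. greater willingness to
forgo money for distant others. Group indicators are coded against the
control baseline, so each group coefficient is that group's shift in
`logk`. Trait comparisons (six-factor personality scales, empathy, risk,
psychopathy subscales) use indicator-coded OLS, a stratified bootstrap
null matched on age-quantile × sex composition drawn from a large
reference population, an L1-penalised logistic classifier with
cross-validated one-standard-error selection, and 36×36 absolute-difference
representational dissimilarity matrices compared by Spearman rank
correlation with a group-block Mantel permutation test (720 relabelings,
enumerated exactly).

## Worked example

```python
from altrudisc import SimConfig, SocialDiscountingModel, score_choice_table
from altrudisc.simulate import generate_cohort, generate_choice_blocks

cfg = SimConfig.choice_sample(seed=1)          # discounting-task sample shape
cohort, truth = generate_cohort(cfg)
choices = generate_choice_blocks(truth, seed=1)
curves, indiff, qc = score_choice_table(choices)
analytic = curves[curves.participant_id.isin(qc.loc[~qc.excluded, "participant_id"])]
print(f"{len(qc)} participants scored, {int(qc.excluded.sum())} excluded for inconsistency")
model = SocialDiscountingModel.from_dataframes(analytic, cohort)
result = model.fit()
print(result.summary())
```

prints

```
275 participants scored, 11 excluded for inconsistency
Hierarchical hyperbolic social-discounting model
========================================================================
Participants: 264    Observations: 1848    Log-likelihood: -6346.381
Converged: True    Residual SD: 4.908    Random effects: v0 + logk
------------------------------------------------------------------------
term                                  est      SE       t        p  95% CI
v0                                 74.914   0.463  161.92   0.0000  [74.003, 75.825]
logk                               -3.361   0.403   -8.34   0.0000  [-4.155, -2.568]
Group[aid_worker]                  -1.788   0.316   -5.66   0.0000  [-2.411, -1.166]
Group[d_kidney_donor]              -1.001   0.296   -3.38   0.0008  [-1.585, -0.417]
Group[heroic_rescuer]              -1.151   0.457   -2.52   0.0123  [-2.050, -0.252]
Group[liver_donor]                 -2.039   0.533   -3.83   0.0002  [-3.089, -0.990]
Group[marrow_donor]                -0.884   0.335   -2.64   0.0089  [-1.544, -0.223]
Group[nd_kidney_donor]             -1.529   0.294   -5.19   0.0000  [-2.109, -0.949]
Age                                 0.013   0.008    1.53   0.1268  [-0.004, 0.029]
Sex (Female)                        0.270   0.202    1.34   0.1826  [-0.128, 0.668]
------------------------------------------------------------------------
Random-effect SDs: v0 6.775, logk 1.492, corr 0.049
```

Reading the table: the simulated controls discount at `logk ≈ −3.4`
(after the uncentered age term), and every altruist group carries a
negative shift — they forgo more for distant others. `v0 ≈ 75` is the
amount a typical participant forgoes for their closest person. The
negative group shifts recover the generative values configured in
`SimConfig` (e.g. non-directed kidney donors at −1.33).
`result.plot_group_curves()` draws the predicted group curves with
confidence ribbons; `result.random_effects` carries per-participant
`(v0_i, logk_i)` predictions, which feed the classifier as the `logk`
predictor.

The same stages run from the shell:

```
altrudisc pipeline --seed 1 --out-dir out/
```

writing `cohort.csv`, `choices.csv`, `curves.csv`, `fit.json`,
`ranef.csv`, `regressions.csv`, `bootstrap.json`, `classifier.json`,
`odds_ratios.csv`, `rdm_*.csv`, `rsa.json` and a `manifest.json` tying
the run together. Per-stage subcommands (`simulate`, `score`,
`fit-nlmm`, `compare`, `bootstrap-null`, `classify`, `rsa`, `validate`)
accept the same CSV contracts for real data exports.

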