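"""End-to-end orchestration of the analysis stages under one manifest."""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from altrudisc import __version__
from altrudisc.config import CONTROL, HEXACO_TRAITS, SimConfig
from altrudisc.io import validate_tables

log = logging.getLogger("altrudisc")

STAGES = ("simulate", "score", "fit", "compare", "bootstrap", "classify", "rsa")


def attach_logk(
    cohort: pd.DataFrame,
    ranef_path=None,
    curves_path=None,
    curves: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join a per-participant ``logk`` column onto the cohort table.

    Prefers model-based per-participant predictions (``ranef.csv``); falls
    back to two-stage per-curve hyperbolic fits when only curves exist.
    """
    cohort = cohort.copy()
    if ranef_path is not None:
        ranef = pd.read_csv(ranef_path)
        lk = ranef.set_index("participant_id")["logk_i"]
    else:
        if curves is None:
            if curves_path is None:
                raise ValueError("need ranef, curves path or curves frame for logk")
            curves = pd.read_csv(curves_path)
        from altrudisc.discounting import fit_hyperbolic_curve

        lk = {}
        for pid, tab in curves.groupby("participant_id"):
            v = dict(zip(tab["distance"], tab["v"]))
            lk[pid] = fit_hyperbolic_curve(v).logk
        lk = pd.Series(lk)
    cohort["logk"] = cohort["participant_id"].map(lk)
    return cohort


def run_rsa_stage(cohort, beliefs, out_dir, n_perm=720, seed=0):
    """Actual-vs-perceived RSA from cohort traits and belief sliders.

    The perceived score matrix comes from per-rater discounting-belief
    curves summarised per target; trait perceptions are emulated by the
    slider-implied generosity when no explicit trait ratings exist, so the
    stage accepts either a trait-rating table (columns target/trait/rating)
    or the belief-slider table produced by the simulator.
    """
    from altrudisc.rsa import build_rdm, mantel_test, scores_from_cohort

    out_dir = Path(out_dir)
    groups = sorted(set(cohort["group"]) - {CONTROL})
    actual_scores = scores_from_cohort(cohort, groups, HEXACO_TRAITS)
    rdm_actual = build_rdm(actual_scores)

    if {"trait", "rating"}.issubset(beliefs.columns):
        from altrudisc.rsa import scores_from_ratings

        perceived_scores = scores_from_ratings(beliefs, groups)
    else:
        # belief sliders: derive per-target per-distance means as pseudo-traits
        piv_mean = beliefs.pivot_table(
            index="target", columns="distance", values="v_beliefs", aggfunc="mean"
        )
        piv_se = beliefs.pivot_table(
            index="target", columns="distance", values="v_beliefs",
            aggfunc=lambda x: np.std(x, ddof=1) / np.sqrt(len(x)),
        )
        from altrudisc.rsa import standardize_scores

        cols = list(piv_mean.columns)[: len(HEXACO_TRAITS)]
        means = piv_mean.loc[groups, cols]
        ses = piv_se.loc[groups, cols]
        means.columns = list(HEXACO_TRAITS)
        ses.columns = list(HEXACO_TRAITS)
        perceived_scores = standardize_scores(means, ses)
    rdm_perceived = build_rdm(perceived_scores)
    result = mantel_test(rdm_actual, rdm_perceived, n_perm=n_perm,
                         n_groups=len(groups), seed=seed)
    rdm_actual.to_csv(out_dir / "rdm_actual.csv")
    rdm_perceived.to_csv(out_dir / "rdm_perceived.csv")
    (out_dir / "rsa.json").write_text(
        json.dumps(
            {
                "rho": result.rho,
                "p": result.p,
                "n_permutations": result.n_permutations,
                "scheme": result.scheme,
                "exact": result.exact,
            },
            indent=2,
        )
    )
    return result


def run_pipeline(config: SimConfig, out_dir: Path) -> dict:
    """Execute all stages, validating intermediate tables, under a manifest."""
    from altrudisc.classify import classify_cohort, fit_logistic_or
    from altrudisc.cohort import bootstrap_matched_null, fit_group_ols
    from altrudisc.discounting import score_choice_table
    from altrudisc.hierarchical import SocialDiscountingModel
    from altrudisc.simulate import (
        generate_belief_ratings,
        generate_choice_blocks,
        generate_cohort,
        generate_population,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "started": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "stages": {},
    }

    def record(stage, **outputs):
        manifest["stages"][stage] = {k: str(v) for k, v in outputs.items()}
        log.info("pipeline stage %s done: %s", stage, list(outputs))

    # simulate
    cohort, true_params = generate_cohort(config)
    choices = generate_choice_blocks(true_params, seed=config.seed)
    population = generate_population(config)
    beliefs = generate_belief_ratings(config)
    cohort.to_csv(out / "cohort.csv", index=False)
    choices.to_csv(out / "choices.csv", index=False)
    population.to_csv(out / "population.csv", index=False)
    beliefs.to_csv(out / "beliefs.csv", index=False)
    record("simulate", cohort=out / "cohort.csv", choices=out / "choices.csv",
           population=out / "population.csv", beliefs=out / "beliefs.csv")

    report = validate_tables(
        {"choices": out / "choices.csv", "cohort": out / "cohort.csv"}
    )
    if not report.ok:
        raise RuntimeError(f"schema validation failed:\n{report.summary()}")

    # score
    curves, indiff, qc = score_choice_table(choices)
    curves.to_csv(out / "curves.csv", index=False)
    indiff.to_csv(out / "indiff.csv", index=False)
    qc.to_csv(out / "qc.csv", index=False)
    record("score", curves=out / "curves.csv", indiff=out / "indiff.csv",
           qc=out / "qc.csv")

    # fit the hierarchical model on consistent participants
    keep = qc.loc[~qc["excluded"], "participant_id"]
    analytic = curves[curves["participant_id"].isin(keep)]
    model = SocialDiscountingModel.from_dataframes(analytic, cohort)
    fit = model.fit()
    (out / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    fit.random_effects.to_csv(out / "ranef.csv", index=False)
    record("fit", fit=out / "fit.json", ranef=out / "ranef.csv")

    # trait comparisons
    frames = []
    for outcome in HEXACO_TRAITS + ("personal_distress",):
        tab = fit_group_ols(cohort, outcome).reset_index(names="term")
        tab.insert(0, "outcome", outcome)
        frames.append(tab)
    pd.concat(frames).to_csv(out / "regressions.csv", index=False)
    record("compare", regressions=out / "regressions.csv")

    # matched bootstrap for honesty-humility
    altruists = cohort[cohort["group"] != CONTROL]
    null = bootstrap_matched_null(
        population, altruists,
        {"altruists": altruists["honesty_humility"].mean(),
         "controls": cohort.loc[cohort["group"] == CONTROL,
                                "honesty_humility"].mean()},
        "honesty_humility", B=1000, m=50, seed=config.seed,
    )
    (out / "bootstrap.json").write_text(json.dumps(
        {"trait": null.trait, "B": null.B, "m": null.m,
         "comparison_means": null.comparison_means,
         "p_one_sided": null.p_one_sided, "p_two_sided": null.p_two_sided,
         "bootstrap_means": null.bootstrap_means.tolist()}, indent=2))
    record("bootstrap", bootstrap=out / "bootstrap.json")

    # classification
    clf_cohort = attach_logk(cohort, ranef_path=out / "ranef.csv")
    clf_cohort = clf_cohort.dropna(subset=["logk"])
    clf_cohort["is_altruist"] = (clf_cohort["group"] != CONTROL).astype(int)
    result = classify_cohort(clf_cohort, seed=config.seed)
    ors = fit_logistic_or(clf_cohort, result.selected)
    (out / "classifier.json").write_text(json.dumps(
        {"lambda_opt": result.lambda_opt, "lambda_1se": result.lambda_1se,
         "selected": result.selected, "test_auroc": result.test_auroc,
         "coef": {k: float(v) for k, v in result.coef.items()}}, indent=2))
    ors.reset_index(names="term").to_csv(out / "odds_ratios.csv", index=False)
    record("classify", classifier=out / "classifier.json",
           odds_ratios=out / "odds_ratios.csv")

    # rsa
    rsa_result = run_rsa_stage(cohort, beliefs, out, seed=config.seed)
    record("rsa", rsa=out / "rsa.json", rdm_actual=out / "rdm_actual.csv",
           rdm_perceived=out / "rdm_perceived.csv")

    manifest["finished"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    for stage in manifest["stages"].values():
        for path in stage.values():
            if not Path(path).exists():
                raise RuntimeError(f"declared output missing: {path}")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
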