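"""Hierarchical hyperbolic model: reductions, recovery, inference."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import least_squares

from altrudisc.config import SimConfig
from altrudisc.discounting import DISTANCES, hyperbolic_value, score_choice_table
from altrudisc.hierarchical import SocialDiscountingModel
from altrudisc.simulate import generate_choice_blocks, generate_cohort


def _direct_simulation(n_control, n_group, seed, logk=(-2.5, -3.5), sd=(5.0, 0.8),
                       v0=75.0, sigma=4.0):
    """Curves drawn straight from the generative mixed model (no scoring)."""
    rng = np.random.default_rng(seed)
    n = n_control + n_group
    group = np.array(["control"] * n_control + ["g"] * n_group)
    lk = np.where(group == "control", logk[0], logk[1]) + rng.normal(0, sd[1], n)
    v0i = v0 + rng.normal(0, sd[0], n)
    dists = np.array(DISTANCES, float)
    V = v0i[:, None] / (1 + np.exp(lk)[:, None] * (dists - 1)[None, :])
    V = V + rng.normal(0, sigma, V.shape)
    X = np.column_stack([np.ones(n), (group == "g").astype(float)])
    return V, X, group


class TestPooledReduction:
    def test_zero_variance_matches_pooled_nls(self):
        V, X, _ = _direct_simulation(25, 15, seed=1, sd=(0.0, 0.0))
        model = SocialDiscountingModel(V, DISTANCES, X, ["Intercept (logk)", "Group[g]"])
        res = model.fit(random_effects=False)
        ns = np.array(DISTANCES) - 1.0

        def resid(p):
            lk = np.clip(X @ p[1:3], -30, 30)
            pred = p[0] / (1 + np.exp(lk)[:, None] * ns[None, :])
            return (V - pred).ravel()

        oracle = least_squares(resid, [60.0, -2.0, 0.0], xtol=1e-15, ftol=1e-15)
        assert np.abs(res.params.to_numpy() - oracle.x).max() < 1e-4

    def test_pooled_loglik_is_gaussian_mle(self):
        V, X, _ = _direct_simulation(20, 10, seed=2)
        model = SocialDiscountingModel(V, DISTANCES, X, ["Intercept (logk)", "Group[g]"])
        res = model.fit(random_effects=False)
        n_obs = V.size
        expected = -0.5 * n_obs * (np.log(2 * np.pi * res.scale) + 1.0)
        assert res.llf == pytest.approx(expected, rel=1e-10)


class TestMarginalLikelihood:
    def test_participant_order_invariance(self):
        V, X, _ = _direct_simulation(20, 15, seed=3)
        names = ["Intercept (logk)", "Group[g]"]
        res_a = SocialDiscountingModel(V, DISTANCES, X, names).fit()
        perm = np.random.default_rng(0).permutation(len(V))
        res_b = SocialDiscountingModel(V[perm], DISTANCES, X[perm], names).fit()
        assert np.abs(res_a.params.to_numpy() - res_b.params.to_numpy()).max() < 1e-3

    def test_group_model_nests_null_model(self):
        V, X, _ = _direct_simulation(25, 20, seed=4)
        names = ["Intercept (logk)", "Group[g]"]
        full = SocialDiscountingModel(V, DISTANCES, X, names).fit()
        null = SocialDiscountingModel(V, DISTANCES, X[:, :1], names[:1]).fit()
        assert full.llf >= null.llf - 1e-4

    def test_quadrature_order_stability(self):
        V, X, _ = _direct_simulation(15, 10, seed=5)
        names = ["Intercept (logk)", "Group[g]"]
        model = SocialDiscountingModel(V, DISTANCES, X, names)
        r5 = model.fit(method="agh", quad_order=5)
        r7 = model.fit(method="agh", quad_order=7, start=r5.theta)
        assert np.abs(r5.params.to_numpy() - r7.params.to_numpy()).max() < 1e-3

    def test_laplace_equals_order_one_quadrature(self):
        V, X, _ = _direct_simulation(10, 8, seed=6)
        names = ["Intercept (logk)", "Group[g]"]
        model = SocialDiscountingModel(V, DISTANCES, X, names)
        theta = model._two_stage_start(unstructured=True)
        cache_a = np.zeros((len(V), 2))
        cache_b = np.zeros((len(V), 2))
        ll_lap = model._marginal_loglik(theta, True, 1, cache_a)
        ll_agh1 = model._marginal_loglik(theta, True, 1, cache_b)
        assert ll_lap == pytest.approx(ll_agh1, rel=1e-12)

    def test_invalid_options_rejected(self):
        V, X, _ = _direct_simulation(5, 5, seed=7)
        model = SocialDiscountingModel(V, DISTANCES, X, ["Intercept (logk)", "Group[g]"])
        with pytest.raises(ValueError):
            model.fit(method="bogus")
        with pytest.raises(ValueError):
            model.fit(quad_order=0)


class TestDesignConstruction:
    def test_rank_deficient_design_names_terms(self):
        n = 20
        X = np.column_stack([np.ones(n), np.arange(n), 2 * np.arange(n)])
        V = np.full((n, 7), 50.0)
        with pytest.raises(ValueError, match="rank deficient"):
            SocialDiscountingModel(V, DISTANCES, X, ["a", "b", "c"])

    def test_from_dataframes_builds_indicators(self, scored_cohort):
        model = SocialDiscountingModel.from_dataframes(
            scored_cohort["analytic_curves"], scored_cohort["cohort"]
        )
        assert model.exog_names[0] == "Intercept (logk)"
        assert sum(n.startswith("Group[") for n in model.exog_names) == 6
        assert "Sex (Female)" in model.exog_names

    def test_missing_baseline_rejected(self, scored_cohort):
        cohort = scored_cohort["cohort"]
        curves = scored_cohort["analytic_curves"]
        with pytest.raises(ValueError, match="baseline"):
            SocialDiscountingModel.from_dataframes(curves, cohort, baseline="nobody")

    def test_interaction_terms_added(self, scored_cohort):
        model = SocialDiscountingModel.from_dataframes(
            scored_cohort["analytic_curves"],
            scored_cohort["cohort"],
            interaction="honesty_humility",
        )
        assert "honesty_humility" in model.exog_names
        assert any("x honesty_humility" in n for n in model.exog_names)


@pytest.fixture(scope="module")
def fitted():
    cfg = SimConfig(
        seed=21,
        group_sizes={"control": 120, "nd_kidney_donor": 60},
        logk_mean={"control": -2.8, "nd_kidney_donor": -4.1},
    )
    cohort, tp = generate_cohort(cfg)
    choices = generate_choice_blocks(tp, seed=21)
    curves, _, qc = score_choice_table(choices)
    curves = curves[
        curves["participant_id"].isin(qc.loc[~qc["excluded"], "participant_id"])
    ]
    model = SocialDiscountingModel.from_dataframes(curves, cohort, covariates=())
    return model.fit()


class TestRecoveryAndInference:
    def test_group_shift_recovered(self, fitted):
        est = fitted.params["Group[nd_kidney_donor]"]
        assert est == pytest.approx(-1.3, abs=0.5)
        ci = fitted.conf_int().loc["Group[nd_kidney_donor]"]
        assert ci["lower"] < est < ci["upper"]

    def test_ci_p_duality(self, fitted):
        ci = fitted.conf_int()
        for name in fitted.params.index:
            excludes_zero = not (ci.loc[name, "lower"] <= 0 <= ci.loc[name, "upper"])
            assert excludes_zero == (fitted.pvalues[name] < 0.05)

    def test_random_effect_predictions_one_per_participant(self, fitted):
        assert len(fitted.random_effects) == fitted.model.n_participants
        assert fitted.cov_re.shape == (2, 2)
        assert np.all(np.diag(fitted.cov_re) >= 0)

    def test_summary_mentions_key_terms(self, fitted):
        text = fitted.summary()
        assert "logk" in text and "Group[nd_kidney_donor]" in text
        assert "Random-effect SDs" in text

    def test_predicted_curves_consistent_with_hyperbola(self, fitted):
        pred = fitted.predict_group_curve("nd_kidney_donor", DISTANCES)
        v0 = fitted.params["v0"]
        lk = fitted.params["logk"] + fitted.params["Group[nd_kidney_donor]"]
        manual = [hyperbolic_value((v0, lk), n) for n in DISTANCES]
        assert pred["v_pred"].to_numpy() == pytest.approx(manual, rel=1e-10)
        assert (pred["ci_lower"] <= pred["v_pred"]).all()
        assert (pred["v_pred"] <= pred["ci_upper"]).all()

    def test_control_curve_starts_at_v0(self, fitted):
        pred = fitted.predict_group_curve(None, [1])
        assert pred["v_pred"].iloc[0] == pytest.approx(fitted.params["v0"], rel=1e-10)

    def test_lower_logk_group_lies_above(self, fitted):
        base = fitted.predict_group_curve(None, DISTANCES)["v_pred"].to_numpy()
        shifted = fitted.predict_group_curve("nd_kidney_donor", DISTANCES)[
            "v_pred"
        ].to_numpy()
        assert (shifted[1:] > base[1:]).all()  # same v0, smaller k -> higher curve

    def test_unknown_group_rejected(self, fitted):
        with pytest.raises(ValueError, match="unknown group"):
            fitted.predict_group_curve("martians")

    def test_plot_smoke(self, fitted):
        import matplotlib

        matplotlib.use("Agg")
        ax = fitted.plot_group_curves(groups=[None, "nd_kidney_donor"])
        assert len(ax.lines) == 2
        import matplotlib.pyplot as plt

        plt.close("all")


def test_null_group_effect_p_uniform():
    """Under a null group effect the Wald p-values are uniform."""
    pvals = []
    for seed in range(60):
        V, X, _ = _direct_simulation(
            30, 30, seed=1000 + seed, logk=(-2.5, -2.5), sd=(5.0, 0.8)
        )
        res = SocialDiscountingModel(
            V, DISTANCES, X, ["Intercept (logk)", "Group[g]"]
        ).fit()
        pvals.append(res.pvalues["Group[g]"])
    stat, p = stats.kstest(pvals, "uniform")
    assert p > 0.01
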