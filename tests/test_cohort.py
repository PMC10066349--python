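"""Cohort statistics: OLS comparisons, demographics, matched bootstrap."""

import numpy as np
import pandas as pd
import pytest

from altrudisc.cohort import (
    bootstrap_matched_null,
    chi_square,
    dichotomize_crt,
    fit_group_ols,
    fit_rating_lmm,
    pooled_t,
)
from altrudisc.config import SimConfig
from altrudisc.simulate import generate_cohort, generate_population
from altrudisc.studydata import demographic_tests, education_table, sex_table


class TestCrt:
    @pytest.mark.parametrize(
        "count,label", [(0, "low"), (1, "low"), (2, "high"), (3, "high")]
    )
    def test_two_or_more_correct_is_high(self, count, label):
        assert dichotomize_crt(count) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_crt(4)


class TestChiSquare:
    def test_sex_balance_from_printed_percentages(self):
        stat, df, p = chi_square(sex_table())
        assert round(stat, 2) == 0.85 and df == 1
        assert p == pytest.approx(0.356, abs=0.005)

    def test_education_imbalance_from_printed_percentages(self):
        stat, df, p = chi_square(education_table())
        assert round(stat, 2) == 16.22 and df == 1
        assert p < 0.001

    def test_proportional_rows_give_zero(self):
        stat, _, p = chi_square([[30, 70], [60, 140]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_to_permutation(self):
        t = np.array([[12, 34], [56, 7]])
        s0, _, _ = chi_square(t)
        s1, _, _ = chi_square(t[::-1])
        s2, _, _ = chi_square(t[:, ::-1])
        assert s0 == pytest.approx(s1) == pytest.approx(s2)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])


class TestPooledT:
    def test_age_difference_from_printed_summaries(self):
        # summaries are themselves rounded to 2 dp, so the recomputed t can
        # sit within one unit in the last printed digit of 6.37
        t, df, p = pooled_t(44.06, 12.50, 347, 37.71, 9.07, 207)
        assert t == pytest.approx(6.37, abs=0.01) and df == 552 and p < 0.001

    def test_equal_means_give_zero(self):
        t, _, p = pooled_t(5.0, 1.0, 50, 5.0, 2.0, 60)
        assert t == 0.0 and p == 1.0

    def test_antisymmetric_in_group_order(self):
        t1, df1, p1 = pooled_t(5.0, 1.0, 40, 4.0, 1.2, 50)
        t2, df2, p2 = pooled_t(4.0, 1.2, 50, 5.0, 1.0, 40)
        assert t1 == -t2 and df1 == df2 and p1 == p2

    def test_all_three_printed_statistics(self):
        res = demographic_tests()
        assert round(res["sex_chi2"][0], 2) == 0.85
        assert round(res["education_chi2"][0], 2) == 16.22
        assert res["age_t"][0] == pytest.approx(6.37, abs=0.01)


class TestGroupOls:
    def test_built_in_trait_shift_detected(self):
        cfg = SimConfig(
            seed=12,
            group_sizes={"control": 200, "aid_worker": 200},
            trait_effects={"honesty_humility": {"aid_worker": 0.5}},
        )
        cohort, _ = generate_cohort(cfg)
        tab = fit_group_ols(cohort, "honesty_humility")
        row = tab.loc["Group[aid_worker]"]
        assert row["estimate"] > 0 and row["p"] < 0.001

    def test_matches_closed_form_least_squares(self):
        cfg = SimConfig(seed=13, group_sizes={"control": 80, "marrow_donor": 60})
        cohort, _ = generate_cohort(cfg)
        tab = fit_group_ols(cohort, "openness")
        X = np.column_stack(
            [
                np.ones(len(cohort)),
                (cohort["group"] == "marrow_donor").astype(float),
                cohort["age"].to_numpy(float),
                (cohort["sex"] == "Female").astype(float),
            ]
        )
        beta = np.linalg.lstsq(X, cohort["openness"].to_numpy(float), rcond=None)[0]
        assert tab["estimate"].to_numpy() == pytest.approx(beta, rel=1e-8)

    def test_duplicating_rows_keeps_coefficients(self):
        cfg = SimConfig(seed=14, group_sizes={"control": 50, "liver_donor": 30})
        cohort, _ = generate_cohort(cfg)
        tab1 = fit_group_ols(cohort, "emotionality")
        tab2 = fit_group_ols(pd.concat([cohort, cohort]), "emotionality")
        assert tab1["estimate"].to_numpy() == pytest.approx(
            tab2["estimate"].to_numpy(), rel=1e-10
        )
        assert (tab2["se"] < tab1["se"]).all()

    def test_constant_outcome_flagged(self):
        cfg = SimConfig(seed=15, group_sizes={"control": 20, "aid_worker": 20})
        cohort, _ = generate_cohort(cfg)
        cohort["flat"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            tab = fit_group_ols(cohort, "flat")
        assert tab.attrs["degenerate"]


@pytest.fixture(scope="module")
def pop_and_target():
    cfg = SimConfig(seed=20, population_size=30000)
    pop = generate_population(cfg)
    cohort, _ = generate_cohort(
        SimConfig(seed=20, group_sizes={"nd_kidney_donor": 150})
    )
    return pop, cohort


class TestBootstrapNull:
    def test_null_mean_gives_half(self, pop_and_target):
        pop, target = pop_and_target
        null = bootstrap_matched_null(
            pop, target, 0.0, "honesty_humility", B=2000, m=50, seed=5
        )
        # comparison at the stratum-weighted population mean -> p near 0.5
        us = pop[pop["country"] == "United States"]
        weighted = 0.0
        for _, row in null.strata.iterrows():
            mask = (
                (us["age"] > (row["age_lo"] if row["age_lo"] > null.strata["age_lo"].min() else -np.inf))
                & (us["age"] <= (row["age_hi"] if row["age_hi"] < null.strata["age_hi"].max() else np.inf))
                & (us["sex"] == row["sex"])
            )
            weighted += us.loc[mask, "honesty_humility"].mean() * row["count"]
        weighted /= null.m
        null2 = bootstrap_matched_null(
            pop, target, weighted, "honesty_humility", B=2000, m=50, seed=5
        )
        assert 0.45 <= null2.p_one_sided["comparison"] <= 0.55

    def test_extreme_comparison_mean(self, pop_and_target):
        pop, target = pop_and_target
        null = bootstrap_matched_null(
            pop, target, 99.0, "honesty_humility", B=500, m=50, seed=1
        )
        assert null.p_one_sided["comparison"] == 0.0  # reported as < 1/B

    def test_fixed_seed_reproducible(self, pop_and_target):
        pop, target = pop_and_target
        a = bootstrap_matched_null(pop, target, 3.0, "openness", B=200, m=50, seed=9)
        b = bootstrap_matched_null(pop, target, 3.0, "openness", B=200, m=50, seed=9)
        assert np.array_equal(a.bootstrap_means, b.bootstrap_means)

    def test_sample_sizes_match_m(self, pop_and_target):
        pop, target = pop_and_target
        null = bootstrap_matched_null(
            pop, target, 3.0, "openness", B=10, m=50, seed=2
        )
        assert null.strata["count"].sum() == 50

    def test_insufficient_stratum_rejected(self, pop_and_target):
        _, target = pop_and_target
        tiny = generate_population(SimConfig(seed=1, population_size=1000)).head(60)
        with pytest.raises(ValueError, match="stratum"):
            bootstrap_matched_null(tiny, target, 3.0, "openness", B=10, m=50)


class TestRatingLmm:
    def _ratings(self, seed, shift=1.0, rater_sd=1.0, n_raters=60):
        rng = np.random.default_rng(seed)
        rows = []
        for r in range(n_raters):
            ri = rng.normal(0, rater_sd)
            for target in ("average person", "donor", "rescuer"):
                mu = 3.0 + (shift if target != "average person" else 0.0)
                rows.append(
                    {
                        "rater_id": r,
                        "target": target,
                        "rating": mu + ri + rng.normal(0, 0.5),
                    }
                )
        return pd.DataFrame(rows)

    def test_contrast_recovery(self):
        hits = 0
        for seed in range(10):
            tab = fit_rating_lmm(self._ratings(seed))
            row = tab.loc["Target[donor]"]
            hits += row["ci_lower"] <= 1.0 <= row["ci_upper"]
        assert hits >= 9

    def test_zero_rater_variance_matches_ols(self):
        import statsmodels.api as sm

        df = self._ratings(3, rater_sd=0.0)
        tab = fit_rating_lmm(df)
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df["target"] == "donor").astype(float),
                (df["target"] == "rescuer").astype(float),
            ]
        )
        ols = sm.OLS(df["rating"].to_numpy(), X).fit()
        assert tab["estimate"].to_numpy() == pytest.approx(ols.params, abs=1e-4)

    def test_single_rater_falls_back_to_ols(self):
        df = self._ratings(0, n_raters=1)
        df = pd.concat([df, self._ratings(1, n_raters=1)])  # replicate ratings
        with pytest.warns(UserWarning, match="single rater"):
            tab = fit_rating_lmm(df)
        assert "Target[donor]" in tab.index

    def test_missing_baseline_rejected(self):
        df = self._ratings(0)
        with pytest.raises(ValueError, match="baseline"):
            fit_rating_lmm(df[df["target"] != "average person"])
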