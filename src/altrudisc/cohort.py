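"""Group comparisons, demographics and the matched bootstrap null.

Trait differences between altruist groups and controls are assessed with
indicator-coded OLS regressions adjusting for age and sex (optionally
education and income).  Demographic balance uses Pearson chi-square (no
continuity correction) and pooled-variance t tests.  Because community
controls are imperfectly matched, a second control distribution is built
by stratified bootstrap: samples drawn without replacement from a large
reference population, with each sample's joint age-quantile x sex
composition matched to the target cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from altrudisc.config import CONTROL

__all__ = [
    "BootstrapNull",
    "bootstrap_matched_null",
    "chi_square",
    "dichotomize_crt",
    "fit_group_ols",
    "fit_rating_lmm",
    "pooled_t",
]


def dichotomize_crt(correct_count: int) -> str:
    """Split cognitive-reflection accuracy into deliberation groups.

    Two or more correct answers (of three) counts as high accuracy (more
    deliberation); one or fewer as low.
    """
    if correct_count not in (0, 1, 2, 3):
        raise ValueError(f"CRT correct count must be in 0..3, got {correct_count}")
    return "high" if correct_count >= 2 else "low"


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Returns ``(statistic, df, p)`` for an r x c count table.
    """
    counts = np.asarray(table, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero marginal")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def pooled_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, int, float]:
    """Two-sample Student t from summary statistics (pooled variance)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def fit_group_ols(
    cohort: pd.DataFrame,
    outcome: str,
    covariates=("age", "sex"),
    baseline: str = CONTROL,
) -> pd.DataFrame:
    """OLS of a trait on group indicators plus covariates.

    Groups are indicator coded against ``baseline``; ``sex`` enters as
    Female = 1, ``education``/``income`` as their binary indicators.
    Returns a coefficient table (estimate, se, t, p, CI) indexed by term.
    Rows with missing outcome or covariates are list-wise dropped.
    """
    if baseline not in set(cohort["group"]):
        raise ValueError(f"baseline group {baseline!r} absent")
    cols = [outcome] + [c for c in covariates if c != "sex"] + (
        ["sex"] if "sex" in covariates else []
    )
    data = cohort.dropna(subset=[c for c in cols if c in cohort.columns])
    y = pd.to_numeric(data[outcome], errors="raise").to_numpy(float)
    degenerate = np.ptp(y) == 0
    if degenerate:
        warnings.warn(f"outcome {outcome!r} is constant; OLS fit is degenerate")
    groups = [g for g in sorted(pd.unique(data["group"])) if g != baseline]
    X = [np.ones(len(data))]
    names = ["Intercept"]
    for g in groups:
        X.append((data["group"] == g).to_numpy(float))
        names.append(f"Group[{g}]")
    for cov in covariates:
        if cov == "sex":
            X.append((data["sex"] == "Female").to_numpy(float))
            names.append("Sex (Female)")
        else:
            X.append(pd.to_numeric(data[cov], errors="raise").to_numpy(float))
            names.append(cov.capitalize() if cov == "age" else cov)
    res = sm.OLS(y, np.column_stack(X)).fit()
    ci = res.conf_int()
    out = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "ci_lower": ci[:, 0],
            "ci_upper": ci[:, 1],
        },
        index=names,
    )
    out.attrs["degenerate"] = bool(degenerate)
    out.attrs["outcome"] = outcome
    out.attrs["nobs"] = int(res.nobs)
    return out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional; group regressions are unadjusted
    by default, mirroring simultaneous multivariate comparison)."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


@dataclass
class BootstrapNull:
    """Null distribution of matched bootstrap sample means for one trait."""

    trait: str
    bootstrap_means: np.ndarray
    B: int
    m: int
    strata: pd.DataFrame
    comparison_means: dict[str, float]
    p_one_sided: dict[str, float] = field(default_factory=dict)
    p_two_sided: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            f"Matched bootstrap null for {self.trait!r}: B={self.B}, m={self.m}",
            f"null mean {self.bootstrap_means.mean():.4f} "
            f"(sd {self.bootstrap_means.std():.4f})",
        ]
        for name, mean in self.comparison_means.items():
            lines.append(
                f"  {name}: mean {mean:.4f}, one-sided p = {self.p_one_sided[name]:.4g},"
                f" two-sided p = {self.p_two_sided[name]:.4g}"
            )
        return "\n".join(lines)


def _stratum_counts(target: pd.DataFrame, m: int, age_quantiles: int):
    """Joint (age-bin x sex) composition of the target, scaled to m draws.

    Age bins come from the target sample's own quantiles; counts are
    allocated by largest remainder so they always sum to m.
    """
    ages = pd.to_numeric(target["age"], errors="raise")
    edges = np.unique(np.quantile(ages, np.linspace(0, 1, age_quantiles + 1)))
    bins = pd.cut(ages, edges, include_lowest=True)
    combo = pd.DataFrame({"age_bin": bins, "sex": target["sex"].to_numpy()})
    props = combo.value_counts(normalize=True, sort=False)
    raw = props * m
    counts = np.floor(raw).astype(int)
    short = m - counts.sum()
    remainder_order = (raw - counts).sort_values(ascending=False).index
    for key in remainder_order[:short]:
        counts[key] += 1
    out = counts[counts > 0].rename("count").reset_index()
    out["age_lo"] = out["age_bin"].map(lambda b: b.left).astype(float)
    out["age_hi"] = out["age_bin"].map(lambda b: b.right).astype(float)
    return out, edges


def bootstrap_matched_null(
    population: pd.DataFrame,
    target_sample: pd.DataFrame,
    comparison_means: dict[str, float] | float,
    trait: str,
    B: int = 5000,
    m: int = 50,
    age_quantiles: int = 4,
    country: str | None = "United States",
    seed: int = 0,
) -> BootstrapNull:
    """Stratified matched bootstrap null distribution of trait means.

    ``B`` samples of size ``m`` are drawn without replacement from the
    reference ``population`` (restricted to ``country`` when that column
    exists), each matched to the joint age-quantile x sex composition of
    ``target_sample``.  One-sided p is the proportion of bootstrap means
    exceeding the comparison mean; two-sided doubles the smaller tail.
    """
    pop = population
    if country is not None and "country" in pop.columns:
        pop = pop[pop["country"] == country]
    strata, edges = _stratum_counts(target_sample, m, age_quantiles)
    # pre-index population members per stratum
    pop_ages = pd.to_numeric(pop["age"], errors="raise").to_numpy(float)
    pop_sex = pop["sex"].to_numpy()
    pop_vals = pd.to_numeric(pop[trait], errors="raise").to_numpy(float)
    pools = []
    for _, row in strata.iterrows():
        lo, hi = row["age_lo"], row["age_hi"]
        # outermost bins absorb out-of-range population ages
        lo_eff = -np.inf if lo <= edges[0] else lo
        hi_eff = np.inf if hi >= edges[-1] else hi
        mask = (pop_ages > lo_eff) & (pop_ages <= hi_eff) & (pop_sex == row["sex"])
        idx = np.where(mask)[0]
        if len(idx) < row["count"]:
            raise ValueError(
                f"stratum (age ({lo}, {hi}], sex {row['sex']}) has only "
                f"{len(idx)} population members; {row['count']} needed"
            )
        pools.append((idx, int(row["count"])))
    rng = np.random.default_rng(seed)
    means = np.empty(B)
    for b in range(B):
        total = 0.0
        for idx, cnt in pools:
            take = rng.choice(idx, size=cnt, replace=False)
            total += pop_vals[take].sum()
        means[b] = total / m
    if not isinstance(comparison_means, dict):
        comparison_means = {"comparison": float(comparison_means)}
    null = BootstrapNull(
        trait=trait,
        bootstrap_means=means,
        B=B,
        m=m,
        strata=strata,
        comparison_means={k: float(v) for k, v in comparison_means.items()},
        seed=seed,
    )
    for name, mean in null.comparison_means.items():
        above = float(np.mean(means > mean))
        below = float(np.mean(means < mean))
        null.p_one_sided[name] = above
        null.p_two_sided[name] = min(1.0, 2.0 * min(above, below))
    return null


def fit_rating_lmm(
    ratings: pd.DataFrame,
    value_col: str = "rating",
    target_col: str = "target",
    rater_col: str = "rater_id",
    baseline: str = "average person",
) -> pd.DataFrame:
    """Random-intercept mixed model of ratings with target contrasts.

    Each rater rates several targets; intercepts vary by rater and every
    target is contrasted against ``baseline`` (ML fit).  With a single
    rater the model degrades to OLS with a warning.
    """
    if baseline not in set(ratings[target_col]):
        raise ValueError(f"baseline target {baseline!r} absent")
    data = ratings[[value_col, target_col, rater_col]].dropna().copy()
    targets = [t for t in sorted(pd.unique(data[target_col])) if t != baseline]
    X = [np.ones(len(data))]
    names = ["Intercept"]
    for t in targets:
        X.append((data[target_col] == t).to_numpy(float))
        names.append(f"Target[{t}]")
    X = np.column_stack(X)
    y = pd.to_numeric(data[value_col], errors="raise").to_numpy(float)
    n_raters = data[rater_col].nunique()
    if n_raters < 2:
        warnings.warn("single rater: falling back to OLS")
        res = sm.OLS(y, X).fit()
        ci = res.conf_int()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=data[rater_col].to_numpy())
            res = model.fit(reml=False)
        ci = np.asarray(res.conf_int())[: len(names)]
    params = np.asarray(res.params)[: len(names)]
    bse = np.asarray(res.bse)[: len(names)]
    tvals = np.asarray(res.tvalues)[: len(names)]
    pvals = np.asarray(res.pvalues)[: len(names)]
    return pd.DataFrame(
        {
            "estimate": params,
            "se": bse,
            "t": tvals,
            "p": pvals,
            "ci_lower": ci[: len(names), 0],
            "ci_upper": ci[: len(names), 1],
        },
        index=names,
    )
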