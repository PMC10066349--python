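"""Penalised classification of altruists versus controls.

25 predictors (discounting rate logk, six personality dimensions, four
empathy subscales, ten risk subscales, three psychopathy subscales) feed
an L1-regularised logistic classifier.  Data are split 80/20 stratified by
label, predictors are standardised on the training partition only, the
penalty path is tuned by 5-fold cross-validated binomial deviance with the
one-standard-error rule (simplest model within one SE of the optimum), and
performance is the rank-based AUROC on the held-out partition.  A
follow-up unpenalised logistic model reports odds ratios for the selected
features plus demographic covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from altrudisc.config import CLASSIFIER_PREDICTORS

__all__ = [
    "CLASSIFIER_PREDICTORS",
    "ClassifierResult",
    "evaluate_auroc",
    "fit_lasso_cv",
    "fit_logistic_or",
    "split_train_test",
]


def split_train_test(labels, fraction: float = 0.8, seed: int = 0):
    """Disjoint, exhaustive, label-stratified train/test index split."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    rng = np.random.default_rng(seed)
    train_idx = []
    for c in classes:
        idx = np.where(y == c)[0]
        rng.shuffle(idx)
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both classes in both parts
        train_idx.append(idx[:n_train])
    train = np.sort(np.concatenate(train_idx))
    test = np.setdiff1d(np.arange(len(y)), train)
    return train, test


@dataclass
class ClassifierResult:
    """Cross-validated L1 path, one-SE selection and test performance."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    lambda_path: np.ndarray
    cv_deviance: np.ndarray
    cv_se: np.ndarray
    lambda_opt: float
    lambda_1se: float
    coef: pd.Series
    intercept: float
    selected: list[str]
    train_mean: pd.Series
    train_sd: pd.Series
    test_auroc: float | None = None
    seed: int | None = None
    dropped_lambdas: list[float] = field(default_factory=list)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor for new data, standardised by the training scaler."""
        Z = (X[self.coef.index] - self.train_mean) / self.train_sd
        return self.intercept + Z.to_numpy(float) @ self.coef.to_numpy(float)


def _deviance(y, p):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return -2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))


def _l1_logistic(Z, y, lam):
    """One L1 logistic fit at penalty lam (objective mean deviance/2 + lam*||b||_1)."""
    n = len(y)
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
        intercept_scaling=1e4, max_iter=5000, tol=1e-8,
    )
    model.fit(Z, y)
    return model


def fit_lasso_cv(
    X: pd.DataFrame,
    y,
    folds: int = 5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
    loss: str = "deviance",
    seed: int = 0,
) -> ClassifierResult:
    """L1 logistic path with k-fold CV and the one-SE rule on training data.

    ``X``/``y`` are the training partition only.  Predictors are
    standardised to mean 0, SD 1 (training statistics).  The grid runs from
    ``lambda_max`` (smallest penalty with an all-zero solution) down four
    decades; the selected penalty is the largest one whose mean CV loss is
    within one standard error of the minimum (fewest features on ties).
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    mu = X.mean()
    sd = X.std(ddof=0).replace(0.0, 1.0)
    Z = ((X - mu) / sd).to_numpy(float)
    n = len(y)
    pbar = y.mean()
    lambda_max = np.abs(Z.T @ (y - pbar)).max() / n
    grid = np.geomspace(lambda_max, lambda_min_ratio * lambda_max, n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    losses = np.full((folds, n_lambdas), np.nan)
    for f, (tr, va) in enumerate(skf.split(Z, y)):
        for j, lam in enumerate(grid):
            try:
                model = _l1_logistic(Z[tr], y[tr], lam)
            except Exception:
                continue
            p = model.predict_proba(Z[va])[:, 1]
            if loss == "deviance":
                losses[f, j] = _deviance(y[va], p)
            elif loss == "misclassification":
                losses[f, j] = np.mean((p >= 0.5) != y[va])
            else:
                raise ValueError(f"unknown CV loss {loss!r}")
    dropped = [float(grid[j]) for j in range(n_lambdas) if np.isnan(losses[:, j]).any()]
    if dropped:
        warnings.warn(f"{len(dropped)} penalty values dropped for non-convergence")
    ok = ~np.isnan(losses).any(axis=0)
    mean_loss = np.nanmean(losses, axis=0)
    se_loss = np.nanstd(losses, axis=0, ddof=1) / np.sqrt(folds)
    jopt = int(np.nanargmin(np.where(ok, mean_loss, np.inf)))
    threshold = mean_loss[jopt] + se_loss[jopt]
    qualifying = np.where(ok & (mean_loss <= threshold))[0]
    j1se = int(qualifying.min())  # grid descends: smallest index = largest lambda
    lam_1se = float(grid[j1se])

    final = _l1_logistic(Z, y, lam_1se)
    coef = pd.Series(final.coef_.ravel(), index=names)
    selected = [nm for nm, c in coef.items() if abs(c) > 1e-10]
    return ClassifierResult(
        train_idx=np.arange(n),
        test_idx=np.array([], dtype=int),
        lambda_path=grid,
        cv_deviance=mean_loss,
        cv_se=se_loss,
        lambda_opt=float(grid[jopt]),
        lambda_1se=lam_1se,
        coef=coef,
        intercept=float(final.intercept_[0]),
        selected=selected,
        train_mean=mu,
        train_sd=sd,
        seed=seed,
        dropped_lambdas=dropped,
    )


def evaluate_auroc(scores, labels) -> float:
    """Rank-based AUROC with midrank ties (the scaled Mann-Whitney U)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = y == np.max(y)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined with a single-class test set")
    ranks = rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classify_cohort(
    cohort: pd.DataFrame,
    predictors=CLASSIFIER_PREDICTORS,
    label_col: str = "is_altruist",
    fraction: float = 0.8,
    folds: int = 5,
    seed: int = 0,
) -> ClassifierResult:
    """End-to-end classification: split, CV path, one-SE fit, test AUROC."""
    cohort = cohort.copy()
    if "crt_high" in predictors and "crt_high" not in cohort.columns:
        cohort["crt_high"] = (
            pd.to_numeric(cohort["crt"], errors="raise") >= 2
        ).astype(int)
    data = cohort.dropna(subset=list(predictors) + [label_col]).reset_index(drop=True)
    y = data[label_col].to_numpy(int)
    train, test = split_train_test(y, fraction=fraction, seed=seed)
    X = data[list(predictors)]
    result = fit_lasso_cv(X.iloc[train], y[train], folds=folds, seed=seed)
    result.train_idx, result.test_idx = train, test
    scores = result.decision_scores(X.iloc[test])
    result.test_auroc = evaluate_auroc(scores, y[test])
    return result


def fit_logistic_or(
    cohort: pd.DataFrame,
    features,
    label_col: str = "is_altruist",
    covariates=("age", "sex", "education", "income"),
) -> pd.DataFrame:
    """Unpenalised logistic model reporting odds ratios (complete cases).

    ``features`` are the classifier-selected traits; demographic covariates
    are appended (sex as Female = 1).  On perfect separation the model is
    refit with a small L2 penalty and flagged via ``attrs['penalized']``.
    """
    cols = list(features) + [c for c in covariates if c != "sex"]
    data = cohort.dropna(subset=[c for c in cols if c in cohort.columns] + [label_col])
    y = data[label_col].to_numpy(float)
    X = [np.ones(len(data))]
    names = ["Intercept"]
    for f in features:
        X.append(pd.to_numeric(data[f], errors="raise").to_numpy(float))
        names.append(f)
    for cov in covariates:
        if cov == "sex":
            X.append((data["sex"] == "Female").to_numpy(float))
            names.append("Sex (Female)")
        else:
            X.append(pd.to_numeric(data[cov], errors="raise").to_numpy(float))
            names.append(cov.capitalize() if cov == "age" else cov)
    X = np.column_stack(X)
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            res = sm.Logit(y, X).fit(disp=0)
        params, bse = np.asarray(res.params), np.asarray(res.bse)
        if not np.isfinite(bse).all() or bse.max() > 1e3:
            raise RuntimeError("separation suspected")
    except Exception:
        penalized = True
        warnings.warn("separation detected; refitting with a small L2 penalty")
        res = sm.Logit(y, X).fit_regularized(
            method="l1", alpha=1e-6, disp=0
        )
        params = np.asarray(res.params)
        bse = np.full_like(params, np.nan)
    z = params / bse
    from scipy import stats as _st

    p = 2 * _st.norm.sf(np.abs(z))
    lo, hi = params - 1.959963984540054 * bse, params + 1.959963984540054 * bse
    out = pd.DataFrame(
        {
            "odds_ratio": np.exp(params),
            "or_ci_lower": np.exp(lo),
            "or_ci_upper": np.exp(hi),
            "log_odds": params,
            "se": bse,
            "z": z,
            "p": p,
        },
        index=names,
    )
    out.attrs["penalized"] = penalized
    out.attrs["nobs"] = int(len(y))
    return out
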