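"""Hierarchical hyperbolic social-discounting model.

Level 1 (within participant, distances centered so that N = 1 maps to 0):

    v_Ni = v0_i / (1 + exp(logk_i) * (N - 1)) + e_Ni,   e_Ni ~ N(0, sigma^2)

Level 2 (between participants):

    v0_i   = beta00 + r0_i
    logk_i = x_i' beta1 + r1_i

with ``x_i`` holding an intercept, altruist-group indicators against the
control baseline, and covariates (age, sex, optionally honesty-humility and
its group interactions, education, income).  The random pair
``(r0_i, r1_i)`` is bivariate normal with unstructured (default) or
diagonal covariance.  The marginal likelihood integrates the random
effects out by a Laplace approximation around each participant's
conditional mode (adaptive Gauss-Hermite quadrature of any order is
available); the curvature uses the Gauss-Newton approximation to the
conditional Hessian, which is exact at a perfectly fitting mode and
standard practice for nonlinear mixed models.

The model class follows the statsmodels idiom: construct from data, call
``fit()``, get a results object with ``params``/``bse``/``pvalues``/
``conf_int()``/``summary()``.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares, minimize

from altrudisc.config import CONTROL
from altrudisc.discounting import DISTANCES, LOGK_BOUNDS, fit_hyperbolic_curve

__all__ = ["SocialDiscountingModel", "SocialDiscountingResults"]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming (near-)collinear columns if the design is rank deficient."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(
            f"level-2 design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms: {bad or names}"
        )


class SocialDiscountingModel:
    """Hyperbolic mixed-effects model of forgone amounts across distances.

    Parameters
    ----------
    v : ndarray, shape (n_participants, n_distances)
        Forgone amounts per participant per distance.
    distances : sequence of int
        The social distances of the columns of ``v``.
    exog_logk : ndarray, shape (n_participants, p)
        Level-2 design for logk, including the intercept column.
    exog_names : sequence of str
        Column names of ``exog_logk``.
    participant_ids : sequence, optional
        Identifiers for the rows of ``v``.
    """

    def __init__(self, v, distances=DISTANCES, exog_logk=None, exog_names=None,
                 participant_ids=None, centered: bool = True):
        self.v = np.asarray(v, dtype=float)
        if self.v.ndim != 2:
            raise ValueError("v must be a (participants x distances) matrix")
        n, m = self.v.shape
        if len(distances) != m:
            raise ValueError("distances must match the columns of v")
        self.distances = np.asarray(distances, dtype=float)
        self.n_shift = self.distances - 1.0 if centered else self.distances.copy()
        self.centered = centered
        if exog_logk is None:
            exog_logk = np.ones((n, 1))
            exog_names = ["Intercept (logk)"]
        self.exog_logk = np.asarray(exog_logk, dtype=float)
        if self.exog_logk.shape[0] != n:
            raise ValueError("exog_logk rows must match participants")
        self.exog_names = list(exog_names)
        _check_rank(self.exog_logk, self.exog_names)
        self.participant_ids = (
            list(participant_ids) if participant_ids is not None else list(range(n))
        )
        self.nobs = n * m
        self.n_participants = n

    # ------------------------------------------------------------------ #
    # construction from tidy tables
    # ------------------------------------------------------------------ #

    @classmethod
    def from_dataframes(
        cls,
        curves: pd.DataFrame,
        cohort: pd.DataFrame,
        covariates: Sequence[str] = ("age", "sex"),
        interaction: str | None = None,
        baseline: str = CONTROL,
    ) -> "SocialDiscountingModel":
        """Build the model from a long curves table and a cohort table.

        ``curves`` columns: participant_id, distance, v.  ``cohort`` columns:
        participant_id, group, plus any covariates.  Groups are indicator
        coded against ``baseline``; ``sex`` is coded Female = 1; passing
        ``interaction="honesty_humility"`` (or another trait) adds the trait
        and its group interactions at level 2.
        """
        wide = curves.pivot_table(
            index="participant_id", columns="distance", values="v"
        ).reindex(columns=list(DISTANCES))
        if wide.isna().any().any():
            bad = wide.index[wide.isna().any(axis=1)].tolist()
            raise ValueError(f"participants with incomplete curves: {bad[:5]}")
        info = cohort.set_index("participant_id").reindex(wide.index)
        if info["group"].isna().any():
            bad = info.index[info["group"].isna()].tolist()
            raise ValueError(f"participants missing from cohort table: {bad[:5]}")
        groups = info["group"]
        if baseline not in set(groups):
            raise ValueError(f"baseline group {baseline!r} absent from data")
        other = [g for g in pd.unique(groups) if g != baseline]
        other.sort()

        cols, names = [np.ones(len(wide))], ["Intercept (logk)"]
        for g in other:
            cols.append((groups == g).to_numpy(float))
            names.append(f"Group[{g}]")
        for cov in covariates:
            if cov == "sex":
                cols.append((info["sex"] == "Female").to_numpy(float))
                names.append("Sex (Female)")
            else:
                vals = pd.to_numeric(info[cov], errors="raise").to_numpy(float)
                if np.isnan(vals).any():
                    raise ValueError(f"missing values in covariate {cov!r}")
                cols.append(vals)
                names.append(cov.capitalize() if cov in ("age",) else cov)
        if interaction is not None:
            trait = pd.to_numeric(info[interaction], errors="raise").to_numpy(float)
            cols.append(trait)
            names.append(interaction)
            for g in other:
                cols.append(trait * (groups == g).to_numpy(float))
                names.append(f"Group[{g}] x {interaction}")
        X = np.column_stack(cols)
        return cls(
            wide.to_numpy(), DISTANCES, X, names, participant_ids=list(wide.index)
        )

    # ------------------------------------------------------------------ #
    # likelihood machinery
    # ------------------------------------------------------------------ #

    @staticmethod
    def _psi_from_theta(t, unstructured: bool):
        """Covariance of (r0, r1) from log-Cholesky parameters."""
        L = np.array(
            [[np.exp(t[0]), 0.0], [t[2] if unstructured else 0.0, np.exp(t[1])]]
        )
        return L @ L.T

    def _inner_modes(self, beta00, lk_fix, sigma2, psi_inv, B, tol=1e-9, maxiter=100):
        """Vectorised damped Newton for the per-participant conditional modes.

        Returns (B, g, h00, h01, h11) where ``g`` is the conditional
        objective at the mode and h* the Gauss-Newton Hessian entries.
        """
        V, ns = self.v, self.n_shift
        p00, p01, p11 = psi_inv[0, 0], psi_inv[0, 1], psi_inv[1, 1]

        def objective(B):
            u = beta00 + B[:, 0]
            lk = np.clip(lk_fix + B[:, 1], -30.0, 30.0)
            D = 1.0 + np.exp(lk)[:, None] * ns[None, :]
            r = V - u[:, None] / D
            quad = (
                p00 * B[:, 0] ** 2 + 2 * p01 * B[:, 0] * B[:, 1] + p11 * B[:, 1] ** 2
            )
            return (r**2).sum(axis=1) / (2.0 * sigma2) + 0.5 * quad

        g_cur = objective(B)
        for _ in range(maxiter):
            u = beta00 + B[:, 0]
            lk = np.clip(lk_fix + B[:, 1], -30.0, 30.0)
            E = np.exp(lk)[:, None] * ns[None, :]
            D = 1.0 + E
            f = u[:, None] / D
            r = V - f
            J0 = 1.0 / D
            J1 = -f * E / D
            gr0 = -(r * J0).sum(1) / sigma2 + p00 * B[:, 0] + p01 * B[:, 1]
            gr1 = -(r * J1).sum(1) / sigma2 + p01 * B[:, 0] + p11 * B[:, 1]
            h00 = (J0 * J0).sum(1) / sigma2 + p00
            h01 = (J0 * J1).sum(1) / sigma2 + p01
            h11 = (J1 * J1).sum(1) / sigma2 + p11
            det = h00 * h11 - h01**2
            s0 = (h11 * gr0 - h01 * gr1) / det
            s1 = (h00 * gr1 - h01 * gr0) / det
            if max(np.abs(gr0).max(), np.abs(gr1).max()) < tol:
                break
            step = np.column_stack([s0, s1])
            lam = np.ones(len(B))
            for _ in range(30):
                cand = B - lam[:, None] * step
                g_new = objective(cand)
                worse = g_new > g_cur + 1e-12
                if not worse.any():
                    break
                lam[worse] *= 0.5
            B = B - lam[:, None] * step
            g_cur = objective(B)
        # final curvature at the mode
        u = beta00 + B[:, 0]
        lk = np.clip(lk_fix + B[:, 1], -30.0, 30.0)
        E = np.exp(lk)[:, None] * ns[None, :]
        D = 1.0 + E
        f = u[:, None] / D
        J0 = 1.0 / D
        J1 = -f * E / D
        h00 = (J0 * J0).sum(1) / sigma2 + p00
        h01 = (J0 * J1).sum(1) / sigma2 + p01
        h11 = (J1 * J1).sum(1) / sigma2 + p11
        return B, objective(B), h00, h01, h11

    def _marginal_loglik(self, theta, unstructured, quad_order, B_cache):
        p = self.exog_logk.shape[1]
        beta00 = theta[0]
        beta1 = theta[1 : 1 + p]
        sigma2 = np.exp(2.0 * theta[1 + p])
        t = theta[2 + p :]
        psi = self._psi_from_theta(t, unstructured)
        sign, logdet_psi = np.linalg.slogdet(psi)
        if sign <= 0:
            return -np.inf
        psi_inv = np.linalg.inv(psi)
        lk_fix = self.exog_logk @ beta1
        B, g, h00, h01, h11 = self._inner_modes(
            beta00, lk_fix, sigma2, psi_inv, B_cache.copy()
        )
        B_cache[:] = B
        det_h = h00 * h11 - h01**2
        n_i = self.v.shape[1]
        base = -0.5 * n_i * np.log(2 * np.pi * sigma2) - 0.5 * logdet_psi
        if quad_order <= 1:
            ll_i = base - g - 0.5 * np.log(det_h)
        else:
            ll_i = base + self._agh_correction(
                beta00, lk_fix, sigma2, psi_inv, B, h00, h01, h11, quad_order
            )
        return float(ll_i.sum())

    def _agh_correction(
        self, beta00, lk_fix, sigma2, psi_inv, B, h00, h01, h11, order
    ):
        """log of the adaptive Gauss-Hermite integral per participant."""
        V, ns = self.v, self.n_shift
        p00, p01, p11 = psi_inv[0, 0], psi_inv[0, 1], psi_inv[1, 1]
        nodes, weights = np.polynomial.hermite.hermgauss(order)
        det_h = h00 * h11 - h01**2
        # Cholesky of H^{-1} per participant, analytic 2x2
        a = h11 / det_h
        b = -h01 / det_h
        c = h00 / det_h
        l11 = np.sqrt(a)
        l21 = b / l11
        l22 = np.sqrt(np.maximum(c - l21**2, 1e-300))

        def objective(Bq):
            u = beta00 + Bq[:, 0]
            lk = np.clip(lk_fix + Bq[:, 1], -30.0, 30.0)
            D = 1.0 + np.exp(lk)[:, None] * ns[None, :]
            r = V - u[:, None] / D
            quad = (
                p00 * Bq[:, 0] ** 2
                + 2 * p01 * Bq[:, 0] * Bq[:, 1]
                + p11 * Bq[:, 1] ** 2
            )
            return (r**2).sum(axis=1) / (2.0 * sigma2) + 0.5 * quad

        terms = []
        for zj, wj in zip(nodes, weights):
            for zk, wk in zip(nodes, weights):
                d0 = np.sqrt(2.0) * l11 * zj
                d1 = np.sqrt(2.0) * (l21 * zj + l22 * zk)
                gq = objective(B + np.column_stack([d0, d1]))
                terms.append(np.log(wj * wk) - gq + zj**2 + zk**2)
        stacked = np.vstack(terms)
        mx = stacked.max(axis=0)
        log_int = mx + np.log(np.exp(stacked - mx).sum(axis=0))
        return np.log(2.0) + np.log(l11 * l22) + log_int

    # ------------------------------------------------------------------ #
    # starting values
    # ------------------------------------------------------------------ #

    def _two_stage_start(self, unstructured):
        v0s, logks = [], []
        for row in self.v:
            par = fit_hyperbolic_curve(row, self.distances, centered=self.centered)
            v0s.append(par.v0)
            logks.append(np.clip(par.logk, LOGK_BOUNDS[0] + 0.5, LOGK_BOUNDS[1] - 0.5))
        v0s, logks = np.array(v0s), np.array(logks)
        beta00 = float(np.mean(v0s))
        beta1, *_ = np.linalg.lstsq(self.exog_logk, logks, rcond=None)
        resid_lk = logks - self.exog_logk @ beta1
        # residual scale from two-stage fitted curves
        pred = v0s[:, None] / (
            1.0 + np.exp(logks)[:, None] * self.n_shift[None, :]
        )
        sigma = max(float(np.std(self.v - pred)), 0.5)
        var0 = max(float(np.var(v0s - beta00)), 0.25)
        var1 = max(float(np.var(resid_lk)), 0.05)
        cov01 = float(np.cov(v0s - beta00, resid_lk)[0, 1]) if len(v0s) > 1 else 0.0
        psi = np.array([[var0, cov01], [cov01, var1]])
        # shrink to positive definite if needed
        w, U = np.linalg.eigh(psi)
        psi = (U * np.maximum(w, 0.05)) @ U.T
        L = np.linalg.cholesky(psi)
        t = [np.log(L[0, 0]), np.log(L[1, 1])]
        if unstructured:
            t.append(L[1, 0])
        return np.concatenate([[beta00], beta1, [np.log(sigma)], t])

    # ------------------------------------------------------------------ #
    # fitting
    # ------------------------------------------------------------------ #

    def fit(
        self,
        method: str = "laplace",
        quad_order: int = 1,
        cov_re: str = "unstructured",
        random_effects: bool = True,
        start: np.ndarray | None = None,
        maxiter: int = 500,
        df_method: str = "t",
    ) -> "SocialDiscountingResults":
        """Maximise the marginal likelihood.

        ``method`` is ``"laplace"`` (default) or ``"agh"`` with
        ``quad_order`` nodes per random-effect dimension; order 1 adaptive
        quadrature is exactly the Laplace approximation.  With
        ``random_effects=False`` both variances are pinned to zero and the
        model reduces to pooled nonlinear least squares.  Inference uses a
        t reference with (participants - level-2 parameters) degrees of
        freedom by default; ``df_method="z"`` switches to normal.
        """
        if not random_effects:
            return self._fit_pooled_nls(df_method)
        if method not in ("laplace", "agh"):
            raise ValueError(f"unknown method {method!r}")
        if quad_order < 1:
            raise ValueError("quadrature order must be >= 1")
        order = quad_order if method == "agh" else 1
        unstructured = cov_re == "unstructured"
        if cov_re not in ("unstructured", "diagonal"):
            raise ValueError(f"unknown random-effect structure {cov_re!r}")

        p = self.exog_logk.shape[1]
        theta0 = np.asarray(start, float) if start is not None else (
            self._two_stage_start(unstructured)
        )
        B_cache = np.zeros((self.n_participants, 2))

        def nll(theta):
            ll = self._marginal_loglik(theta, unstructured, order, B_cache)
            return -ll if np.isfinite(ll) else 1e12

        bounds = (
            [(-50.0, 250.0)]
            + [(LOGK_BOUNDS[0], LOGK_BOUNDS[1])]
            + [(None, None)] * (p - 1)
            + [(np.log(1e-2), np.log(1e3))]
            + [(-8.0, 4.0), (-8.0, 4.0)]
            + ([(-20.0, 20.0)] if unstructured else [])
        )
        res = minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-5, "eps": 1e-6},
        )
        if not res.success:
            # one restart from the stopping point with a finer difference step
            res2 = minimize(
                nll,
                res.x,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-4,
                         "eps": 1e-7},
            )
            if res2.fun <= res.fun:
                res = res2
        theta = res.x
        llf = -res.fun
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                f"marginal-likelihood optimisation did not converge: {res.message}"
            )
        # final conditional modes and curvature at the optimum
        beta00 = theta[0]
        beta1 = theta[1 : 1 + p]
        sigma2 = np.exp(2.0 * theta[1 + p])
        psi = self._psi_from_theta(theta[2 + p :], unstructured)
        psi_inv = np.linalg.inv(psi)
        lk_fix = self.exog_logk @ beta1
        B, _, _, _, _ = self._inner_modes(beta00, lk_fix, sigma2, psi_inv, B_cache)

        def nll_fresh(th):
            # history-free evaluation for curvature: restart the inner
            # solver from the converged modes every time
            cache = B.copy()
            ll = self._marginal_loglik(th, unstructured, order, cache)
            return -ll if np.isfinite(ll) else 1e12

        cov_params, singular = self._cov_params(theta, nll_fresh)
        return SocialDiscountingResults(
            model=self,
            theta=theta,
            llf=llf,
            converged=converged,
            cov_theta=cov_params,
            singular_information=singular,
            unstructured=unstructured,
            ranef=B,
            df_method=df_method,
            pooled=False,
        )

    def _cov_params(self, theta, nll):
        """Observed-information covariance by central-difference Hessian."""
        k = len(theta)
        h = 1e-4 * np.maximum(np.abs(theta), 1.0)
        H = np.zeros((k, k))
        f0 = nll(theta)
        # diagonal terms
        fp = np.empty(k)
        fm = np.empty(k)
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            fp[i] = nll(theta + e)
            fm[i] = nll(theta - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                fpp = nll(theta + ei + ej)
                fmm = nll(theta - ei - ej)
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
                ) / (2 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            singular = False
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            singular = True
        d = np.diag(cov)
        if np.any(d < 0):
            singular = True
        return cov, singular

    def _fit_pooled_nls(self, df_method):
        """All random-effect variance pinned to zero: pooled NLS."""
        p = self.exog_logk.shape[1]
        V, ns, X = self.v, self.n_shift, self.exog_logk

        def resid(par):
            beta00, beta1 = par[0], par[1 : 1 + p]
            lk = np.clip(X @ beta1, -30.0, 30.0)
            pred = beta00 / (1.0 + np.exp(lk)[:, None] * ns[None, :])
            return (V - pred).ravel()

        start = self._two_stage_start(unstructured=False)[: 1 + p]
        sol = least_squares(resid, start, method="trf", xtol=1e-14, ftol=1e-14)
        n_obs = V.size
        sse = float(sol.fun @ sol.fun)
        sigma2 = sse / n_obs
        llf = -0.5 * n_obs * (np.log(2 * np.pi * sigma2) + 1.0)
        J = sol.jac
        cov_beta = sigma2 * np.linalg.inv(J.T @ J)
        k = 1 + p
        theta = np.concatenate([sol.x, [0.5 * np.log(sigma2)], [-np.inf, -np.inf, 0.0]])
        cov_theta = np.zeros((len(theta), len(theta)))
        cov_theta[:k, :k] = cov_beta
        return SocialDiscountingResults(
            model=self,
            theta=theta,
            llf=llf,
            converged=bool(sol.success),
            cov_theta=cov_theta,
            singular_information=False,
            unstructured=True,
            ranef=np.zeros((self.n_participants, 2)),
            df_method=df_method,
            pooled=True,
        )


class SocialDiscountingResults:
    """Fitted hierarchical discounting model (Table-1-style inference).

    Attributes
    ----------
    params : pandas.Series
        Fixed effects: v0 intercept followed by the level-2 logk terms.
    bse, tvalues, pvalues : pandas.Series
        Wald inference from the observed-information inverse.
    cov_re : ndarray (2, 2)
        Estimated covariance of the (v0, logk) random effects.
    scale : float
        Residual variance of ``e_Ni``.
    random_effects : pandas.DataFrame
        Conditional modes and per-participant predicted (v0_i, logk_i).
    """

    def __init__(self, model, theta, llf, converged, cov_theta,
                 singular_information, unstructured, ranef, df_method, pooled):
        self.model = model
        self.theta = theta
        self.llf = float(llf)
        self.converged = converged
        self.singular_information = singular_information
        self.pooled = pooled
        p = model.exog_logk.shape[1]
        self._p = p
        names = ["v0"] + list(model.exog_names)
        names[1] = "logk"  # the level-2 intercept is the control logk
        self.param_names = names
        self.params = pd.Series(theta[: 1 + p], index=names)
        self.scale = float(np.exp(2.0 * theta[1 + p]))
        if pooled:
            self.cov_re = np.zeros((2, 2))
        else:
            self.cov_re = SocialDiscountingModel._psi_from_theta(
                theta[2 + p :], unstructured
            )
        self.cov_params_full = cov_theta
        cov_beta = cov_theta[: 1 + p, : 1 + p]
        with np.errstate(invalid="ignore"):
            self.bse = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)
        if singular_information:
            self.bse[:] = np.nan
        self.df_method = df_method
        self.df_resid = max(model.n_participants - p, 1)
        self.tvalues = self.params / self.bse
        if df_method == "t":
            self.pvalues = pd.Series(
                2 * stats.t.sf(np.abs(self.tvalues), self.df_resid), index=names
            )
            self._crit = stats.t.ppf(0.975, self.df_resid)
        else:
            self.pvalues = pd.Series(
                2 * stats.norm.sf(np.abs(self.tvalues)), index=names
            )
            self._crit = stats.norm.ppf(0.975)
        lk_fix = model.exog_logk @ theta[1 : 1 + p]
        self.random_effects = pd.DataFrame(
            {
                "participant_id": model.participant_ids,
                "r0": ranef[:, 0],
                "r1": ranef[:, 1],
                "v0_i": theta[0] + ranef[:, 0],
                "logk_i": lk_fix + ranef[:, 1],
            }
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.df_method == "t":
            crit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        else:
            crit = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - crit * self.bse,
                "upper": self.params + crit * self.bse,
            }
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        """Conditional fitted curves (participant modes plugged in)."""
        v0 = self.random_effects["v0_i"].to_numpy()[:, None]
        lk = self.random_effects["logk_i"].to_numpy()[:, None]
        return v0 / (1.0 + np.exp(lk) * self.model.n_shift[None, :])

    def coefficient_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def predict_group_curve(
        self,
        group: str | None,
        distances=DISTANCES,
        covariate_values: dict | None = None,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Predicted group-level curve with delta-method confidence ribbons.

        ``group=None`` (or the baseline label) predicts the control curve.
        Continuous covariates enter at their sample means unless pinned in
        ``covariate_values`` (keys are level-2 term names).
        """
        model = self.model
        x = model.exog_logk.mean(axis=0).copy()
        gname = f"Group[{group}]"
        group_terms = [n for n in model.exog_names if n.startswith("Group[")]
        for j, name in enumerate(model.exog_names):
            if name.startswith("Group["):
                x[j] = 1.0 if name == gname else 0.0
        if group is not None and gname not in model.exog_names and group_terms:
            raise ValueError(f"unknown group {group!r}")
        if covariate_values:
            for name, val in covariate_values.items():
                if name not in model.exog_names:
                    raise ValueError(f"unknown level-2 term {name!r}")
                x[model.exog_names.index(name)] = val

        p = self._p
        beta00 = self.params.iloc[0]
        beta1 = self.theta[1 : 1 + p]
        lk = float(x @ beta1)
        ns = np.asarray(distances, float) - (1.0 if model.centered else 0.0)
        denom = 1.0 + np.exp(lk) * ns
        pred = beta00 / denom
        # gradient wrt (beta00, beta1)
        dv_dlk = -beta00 * np.exp(lk) * ns / denom**2
        grad = np.zeros((len(ns), 1 + p))
        grad[:, 0] = 1.0 / denom
        grad[:, 1:] = dv_dlk[:, None] * x[None, :]
        cov_beta = self.cov_params_full[: 1 + p, : 1 + p]
        var = np.einsum("ij,jk,ik->i", grad, cov_beta, grad)
        se = np.sqrt(np.maximum(var, 0.0))
        return pd.DataFrame(
            {
                "distance": np.asarray(distances),
                "v_pred": pred,
                "se": se,
                "ci_lower": pred - self._crit * se,
                "ci_upper": pred + self._crit * se,
            }
        )

    def plot_group_curves(self, groups=None, distances=None, ax=None):
        """Plot predicted discounting curves with CI ribbons per group.

        ``groups`` defaults to every indicator-coded group plus the
        baseline (``None`` entry).  Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if distances is None:
            distances = np.unique(
                np.concatenate([self.model.distances, np.arange(1, 101)])
            )
        if groups is None:
            groups = [None] + [
                n[len("Group["):-1]
                for n in self.model.exog_names
                if n.startswith("Group[")
            ]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        for g in groups:
            pred = self.predict_group_curve(g, distances)
            label = g if g is not None else "control"
            (line,) = ax.plot(pred["distance"], pred["v_pred"], label=label)
            ax.fill_between(
                pred["distance"], pred["ci_lower"], pred["ci_upper"],
                alpha=0.15, color=line.get_color(),
            )
        ax.set_xlabel("social distance N")
        ax.set_ylabel("amount willing to forgo ($)")
        ax.set_xscale("log")
        ax.legend(fontsize=8)
        return ax

    def summary(self) -> str:
        lines = [
            "Hierarchical hyperbolic social-discounting model",
            "=" * 72,
            f"Participants: {self.model.n_participants}    "
            f"Observations: {self.model.nobs}    "
            f"Log-likelihood: {self.llf:.3f}",
            f"Converged: {self.converged}    "
            f"Residual SD: {np.sqrt(self.scale):.3f}    "
            f"Random effects: {'pooled NLS (none)' if self.pooled else 'v0 + logk'}",
            "-" * 72,
            f"{'term':<32}{'est':>9}{'SE':>8}{'t':>8}{'p':>9}  95% CI",
        ]
        tab = self.coefficient_table()
        for name, row in tab.iterrows():
            lines.append(
                f"{name:<32}{row['estimate']:>9.3f}{row['se']:>8.3f}"
                f"{row['t']:>8.2f}{row['p']:>9.4f}  "
                f"[{row['ci_lower']:.3f}, {row['ci_upper']:.3f}]"
            )
        if not self.pooled:
            sd0, sd1 = np.sqrt(np.diag(self.cov_re))
            corr = self.cov_re[0, 1] / (sd0 * sd1) if sd0 > 0 and sd1 > 0 else 0.0
            lines += [
                "-" * 72,
                f"Random-effect SDs: v0 {sd0:.3f}, logk {sd1:.3f}, corr {corr:.3f}",
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable fit record (coefficients, covariances, loglik)."""
        tab = self.coefficient_table()
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "table": {
                name: {c: float(row[c]) for c in tab.columns}
                for name, row in tab.iterrows()
            },
            "cov_re": self.cov_re.tolist(),
            "sigma2": self.scale,
            "loglik": self.llf,
            "converged": self.converged,
            "n_participants": self.model.n_participants,
        }
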