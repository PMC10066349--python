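"""Representational similarity of perceived versus actual group traits.

For six groups by six trait dimensions, each group/trait cell is scored as
mean divided by its standard error, then z-scored across groups within
each trait.  Pairwise absolute differences among the 36 cells form a
36 x 36 representational dissimilarity matrix (RDM) with 630 unique
lower-triangle pairs.  Two RDMs are compared by Spearman rank correlation
of their lower triangles; significance comes from a Mantel permutation
test that shuffles the six group labels jointly over rows and columns
(720 distinct relabelings, enumerated exactly by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "RSAResult",
    "build_rdm",
    "compare_rdms",
    "lower_triangle",
    "mantel_test",
    "standardize_scores",
]

N_GROUP_PERMUTATIONS = 720  # 6!


def standardize_scores(
    means: pd.DataFrame, ses: pd.DataFrame, ddof: int = 0
) -> pd.DataFrame:
    """Group x trait score matrix: mean/SE, z-scored across groups per trait.

    ``means`` and ``ses`` are (groups x traits) frames with matching labels.
    Dividing by the standard error converts each cell to a t-like score;
    z-scoring (population convention, ``ddof=0``) then places the groups on
    a common scale within each trait dimension.
    """
    if not means.index.equals(ses.index) or not means.columns.equals(ses.columns):
        raise ValueError("means and ses must share row/column labels")
    if (ses.to_numpy() <= 0).any():
        raise ValueError("standard errors must be positive")
    t = means / ses
    mu = t.mean(axis=0)
    sd = t.std(axis=0, ddof=ddof)
    sd = sd.replace(0.0, 1.0)  # all-equal column -> zero scores
    return (t - mu) / sd


def build_rdm(scores: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Absolute-difference dissimilarity matrix over all group/trait cells.

    A (groups x traits) score frame is flattened group-major into
    ``groups*traits`` cells labelled ``(group, trait)``; entry (i, j) is
    ``|s_i - s_j|``.
    """
    if isinstance(scores, pd.DataFrame):
        flat = scores.stack()
        labels = pd.MultiIndex.from_tuples(flat.index, names=["group", "trait"])
        vec = flat.to_numpy(float)
    else:
        vec = np.asarray(scores, float).ravel()
        labels = pd.RangeIndex(len(vec))
    if not np.isfinite(vec).all():
        raise ValueError("scores must be finite")
    mat = np.abs(vec[:, None] - vec[None, :])
    return pd.DataFrame(mat, index=labels, columns=labels)


def lower_triangle(rdm: pd.DataFrame | np.ndarray) -> np.ndarray:
    """The unique off-diagonal pairs (row-major lower triangle)."""
    m = np.asarray(rdm, float)
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def compare_rdms(rdm_a, rdm_b) -> float:
    """Spearman rank correlation of the two lower triangles (midrank ties)."""
    ta, tb = lower_triangle(rdm_a), lower_triangle(rdm_b)
    if ta.shape != tb.shape:
        raise ValueError("RDMs must have matching shape")
    if np.ptp(ta) == 0 or np.ptp(tb) == 0:
        raise ValueError("Spearman rho undefined on a zero-variance triangle")
    rho, _ = spearmanr(ta, tb)
    return float(rho)


@dataclass
class RSAResult:
    """Observed RDM correspondence and its Mantel permutation null."""

    rho: float
    p: float
    null_rho: np.ndarray
    n_permutations: int
    scheme: str
    exact: bool
    seed: int | None = None

    def summary(self) -> str:
        return (
            f"Spearman rho = {self.rho:.4f}, Mantel p = {self.p:.4g} "
            f"({'exact enumeration of' if self.exact else 'sampled'} "
            f"{self.n_permutations} {self.scheme} permutations)"
        )


def _cell_permutation(group_perm, n_groups: int, n_traits: int) -> np.ndarray:
    """Cell index permutation induced by permuting group blocks."""
    out = np.empty(n_groups * n_traits, dtype=int)
    for g_new, g_old in enumerate(group_perm):
        out[g_new * n_traits : (g_new + 1) * n_traits] = np.arange(
            g_old * n_traits, (g_old + 1) * n_traits
        )
    return out


def mantel_test(
    rdm_a,
    rdm_b,
    n_perm: int = 5000,
    scheme: str = "group-block",
    n_groups: int = 6,
    seed: int = 0,
) -> RSAResult:
    """Mantel permutation test of RDM correspondence.

    Under ``scheme="group-block"`` each permutation reassigns the six group
    identities, moving each group's block of trait cells jointly over rows
    and columns of the second RDM; only 720 distinct relabelings exist, so
    whenever ``n_perm >= 720`` the full set is enumerated instead of
    sampled.  ``scheme="cells"`` permutes all cell labels freely (sampled).
    The p-value counts permuted statistics >= the observed rho, including
    the identity relabeling in the exact case (conservative).
    """
    A = np.asarray(rdm_a, float)
    B = np.asarray(rdm_b, float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("RDMs must be square with matching shape")
    n_cells = A.shape[0]
    obs = compare_rdms(A, B)
    ta = lower_triangle(A)
    i, j = np.tril_indices(n_cells, k=-1)
    rank_a = pd.Series(ta).rank().to_numpy()

    def rho_for(perm):
        Bp = B[np.ix_(perm, perm)]
        tb = Bp[i, j]
        rank_b = pd.Series(tb).rank().to_numpy()
        ra = rank_a - rank_a.mean()
        rb = rank_b - rank_b.mean()
        return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))

    if scheme == "group-block":
        if n_cells % n_groups:
            raise ValueError("cell count must be divisible by the group count")
        n_traits = n_cells // n_groups
        exact = n_perm >= N_GROUP_PERMUTATIONS
        if exact:
            perms = [
                _cell_permutation(gp, n_groups, n_traits)
                for gp in permutations(range(n_groups))
            ]
        else:
            rng = np.random.default_rng(seed)
            perms = [
                _cell_permutation(rng.permutation(n_groups), n_groups, n_traits)
                for _ in range(n_perm)
            ]
    elif scheme == "cells":
        exact = False
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n_cells) for _ in range(n_perm)]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    null = np.array([rho_for(p) for p in perms])
    count = int(np.sum(null >= obs - 1e-12))
    p = count / len(null)
    return RSAResult(
        rho=obs,
        p=float(p),
        null_rho=null,
        n_permutations=len(null),
        scheme=scheme,
        exact=exact,
        seed=seed,
    )


def scores_from_cohort(
    cohort: pd.DataFrame, groups, traits
) -> pd.DataFrame:
    """Standardized score matrix straight from participant-level data."""
    means = pd.DataFrame(index=list(groups), columns=list(traits), dtype=float)
    ses = means.copy()
    for g in groups:
        sub = cohort[cohort["group"] == g]
        for t in traits:
            vals = pd.to_numeric(sub[t], errors="raise").dropna()
            means.loc[g, t] = vals.mean()
            ses.loc[g, t] = vals.std(ddof=1) / np.sqrt(len(vals))
    return standardize_scores(means, ses)


def scores_from_ratings(
    ratings: pd.DataFrame,
    groups,
    traits=None,
    target_col: str = "target",
    trait_col: str = "trait",
    value_col: str = "rating",
) -> pd.DataFrame:
    """Standardized score matrix from a long rater x target x trait table."""
    piv_mean = ratings.pivot_table(
        index=target_col, columns=trait_col, values=value_col, aggfunc="mean"
    )
    piv_se = ratings.pivot_table(
        index=target_col, columns=trait_col, values=value_col,
        aggfunc=lambda x: np.std(x, ddof=1) / np.sqrt(len(x)),
    )
    if traits is None:
        traits = list(piv_mean.columns)
    means = piv_mean.loc[list(groups), list(traits)]
    ses = piv_se.loc[list(groups), list(traits)]
    return standardize_scores(means, ses)
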