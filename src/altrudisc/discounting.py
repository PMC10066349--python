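"""Scoring of social-discounting choice blocks.

A choice block presents nine binary decisions for one social distance ``N``:
keep a selfish amount (``$155`` down to ``$75`` in ``$10`` steps) for
yourself, or keep ``$75`` and give ``$75`` to person number ``N`` on your
list of the 100 closest people.  The indifference point is the selfish
amount at which the respondent is equally likely to keep or share; the
amount willing to forgo is ``v = indifference - 75``.  Across the seven
distances the ``v`` values trace a discounting curve that is summarised
either model-agnostically by a normalised area under the curve (AUC) or
parametrically by a hyperbola ``v = v0 / (1 + k * (N - 1))`` with the
discounting rate modelled on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit

#: social distances probed by the task (rank on the closeness list).
DISTANCES: tuple[int, ...] = (1, 2, 5, 10, 20, 50, 100)

#: selfish amounts of the nine trials, in descending order.
AMOUNTS: tuple[int, ...] = tuple(range(155, 65, -10))

#: dollars kept under the sharing option.
SHARE_KEPT = 75.0

#: indifference point assumed when every trial is the selfish choice.
FLOOR_INDIFFERENCE = 70.0

#: indifference point assumed when every trial is the generous choice.
CEILING_INDIFFERENCE = 160.0

#: search box for logk during curve fitting; far outside the plausible
#: range, present only to keep exp(logk)*N finite.
LOGK_BOUNDS = (-10.0, 5.0)


@dataclass(frozen=True)
class IndifferencePoint:
    """Indifference point for one distance, with provenance of the estimate."""

    distance: int
    amount: float
    method: str  # logistic | assumed_floor | assumed_ceiling | midpoint_fallback
    b0: float | None = None
    b1: float | None = None


@dataclass(frozen=True)
class HyperbolicParams:
    """Parameters of one hyperbolic discounting curve, rate on the log scale."""

    v0: float
    logk: float
    converged: bool = True
    identifiable: bool = True

    @property
    def k(self) -> float:
        return float(np.exp(self.logk))


@dataclass
class DiscountCurve:
    """Forgone amounts for one participant across the seven distances."""

    participant_id: object
    v: dict[int, float] = field(default_factory=dict)
    auc: float | None = None


def _order_block(amounts: Iterable[float], choices: Iterable[int]):
    amounts = np.asarray(list(amounts), dtype=float)
    choices = np.asarray(list(choices), dtype=int)
    if amounts.shape != (9,) or sorted(amounts) != sorted(AMOUNTS):
        raise ValueError(
            f"a choice block requires the nine amounts {AMOUNTS}, got {amounts}"
        )
    if not np.isin(choices, (0, 1)).all():
        raise ValueError("choices must be binary (1 = share, 0 = keep)")
    order = np.argsort(-amounts)
    return amounts[order], choices[order]


def count_switches(amounts: Iterable[float], choices: Iterable[int]) -> int:
    """Number of keep/share alternations along the descending amount ladder.

    Switches are defined on the value ladder, so the block is re-ordered by
    descending amount regardless of presentation order.
    """
    _, c = _order_block(amounts, choices)
    return int(np.sum(np.abs(np.diff(c))))


def flag_inconsistent(blocks: Mapping[int, tuple]) -> bool:
    """True if any of the participant's seven blocks switches more than twice.

    ``blocks`` maps distance -> (amounts, choices).  Participants flagged
    here are excluded from discounting analyses; the rule is strict
    ("more than two"), so exactly two switches is still consistent.
    """
    missing = set(DISTANCES) - set(blocks)
    if missing:
        raise ValueError(f"missing choice blocks for distances {sorted(missing)}")
    return any(count_switches(*blocks[n]) > 2 for n in DISTANCES)


def _logistic_mle(amounts: np.ndarray, choices: np.ndarray, maxiter: int = 200):
    """Newton-Raphson MLE of P(share) on amount; returns (b0, b1, ok)."""
    x = np.column_stack([np.ones_like(amounts), amounts])
    beta = np.zeros(2)
    # crude but stable start: slope from endpoint share rates
    for _ in range(maxiter):
        eta = x @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        grad = x.T @ (choices - p)
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(2), grad)
        except np.linalg.LinAlgError:
            return beta[0], beta[1], False
        beta = beta + step
        if np.abs(grad).max() < 1e-9:
            break
        if np.abs(beta).max() > 1e6:  # drifting towards separation
            return beta[0], beta[1], False
    return beta[0], beta[1], True


def estimate_indifference(
    amounts: Iterable[float], choices: Iterable[int], distance: int = 0
) -> IndifferencePoint:
    """Indifference point of one block.

    All-keep blocks are assigned $70 and all-share blocks $160.  Perfectly
    separated responses make the logistic MLE divergent while ``-b0/b1``
    converges to the midpoint of the two amounts bracketing the switch, so
    that midpoint is returned analytically.  Otherwise the point solves
    ``P(share) = 0.5`` from a logistic fit of choice on amount, clamped to
    the $[70, 160]$ range of the assumed endpoints.
    """
    a, c = _order_block(amounts, choices)
    if c.sum() == 0:
        return IndifferencePoint(distance, FLOOR_INDIFFERENCE, "assumed_floor")
    if c.sum() == 9:
        return IndifferencePoint(distance, CEILING_INDIFFERENCE, "assumed_ceiling")

    share_amounts = a[c == 1]
    keep_amounts = a[c == 0]
    # perfect separation in either direction: MLE diverges, -b0/b1 -> midpoint
    if share_amounts.max() < keep_amounts.min():
        mid = (share_amounts.max() + keep_amounts.min()) / 2.0
        return IndifferencePoint(distance, float(mid), "midpoint_fallback")
    if keep_amounts.max() < share_amounts.min():
        mid = (keep_amounts.max() + share_amounts.min()) / 2.0
        return IndifferencePoint(distance, float(mid), "midpoint_fallback")

    b0, b1, ok = _logistic_mle(a, c)
    if not ok or b1 >= -1e-8:
        # degenerate fit (no slope, or share probability *rising* with the
        # selfish amount): fall back to the mean keep/share midpoint
        mid = (share_amounts.mean() + keep_amounts.mean()) / 2.0
        return IndifferencePoint(distance, float(mid), "midpoint_fallback")
    point = float(np.clip(-b0 / b1, FLOOR_INDIFFERENCE, CEILING_INDIFFERENCE))
    return IndifferencePoint(distance, point, "logistic", float(b0), float(b1))


def to_forgone(ip: IndifferencePoint | float) -> float:
    """Amount willing to forgo: indifference point minus the $75 kept when sharing."""
    amount = ip.amount if isinstance(ip, IndifferencePoint) else float(ip)
    if not FLOOR_INDIFFERENCE <= amount <= CEILING_INDIFFERENCE:
        raise ValueError(f"indifference point {amount} outside [70, 160]")
    return amount - SHARE_KEPT


def hyperbolic_value(
    params: HyperbolicParams | tuple[float, float], distance, centered: bool = True
):
    """Hyperbolic value ``v0 / (1 + exp(logk) * N')`` at the given distance(s).

    With ``centered=True`` the distance enters as ``N - 1`` so that ``v0``
    is the value at the closest person (N=1); uncentered uses ``N`` directly.
    """
    if isinstance(params, HyperbolicParams):
        v0, logk = params.v0, params.logk
    else:
        v0, logk = params
    n = np.asarray(distance, dtype=float)
    if np.any(n < 1):
        raise ValueError("social distance must be >= 1")
    shift = n - 1.0 if centered else n
    out = v0 / (1.0 + np.exp(logk) * shift)
    return float(out) if np.isscalar(distance) else out


def compute_auc(
    v: Mapping[int, float] | Iterable[float],
    distances: Iterable[int] = DISTANCES,
    norm: str = "max-possible",
) -> float:
    """Normalised area under the discounting curve.

    Distances are scaled by the maximum distance and forgone amounts by the
    maximum forgone amount; straight lines connect the observed points and
    the trapezoid areas are summed over the observed span.  ``norm`` picks
    the ``v`` denominator: ``"max-possible"`` uses the task ceiling of $85
    (default; always defined), ``"participant-max"`` uses the participant's
    own largest ``v`` (undefined when that is not positive).
    """
    if isinstance(v, Mapping):
        distances = sorted(v)
        values = np.array([v[n] for n in distances], dtype=float)
    else:
        values = np.asarray(list(v), dtype=float)
        distances = list(distances)
    if len(values) != len(distances):
        raise ValueError("v and distances must align")
    if norm == "max-possible":
        vmax = CEILING_INDIFFERENCE - SHARE_KEPT
    elif norm == "participant-max":
        vmax = values.max()
        if vmax <= 0:
            raise ValueError("participant-max normalisation undefined for v <= 0")
    else:
        raise ValueError(f"unknown AUC normalisation {norm!r}")
    x = np.asarray(distances, dtype=float) / max(distances)
    y = values / vmax
    return float(np.trapezoid(y, x))


def _profile_sse(logk: float, n_shift: np.ndarray, v: np.ndarray):
    """SSE profiled over v0 (linear given logk); returns (sse, v0hat)."""
    w = 1.0 / (1.0 + np.exp(logk) * n_shift)
    denom = float(w @ w)
    v0 = float(v @ w) / denom if denom > 0 else 0.0
    resid = v - v0 * w
    return float(resid @ resid), v0


def fit_hyperbolic_curve(
    v: Mapping[int, float] | Iterable[float],
    distances: Iterable[int] = DISTANCES,
    centered: bool = True,
    grid_size: int = 121,
) -> HyperbolicParams:
    """Least-squares hyperbolic fit to one curve of forgone amounts.

    The sum of squares is profiled over ``v0`` (conditionally linear) and
    minimised over ``logk`` on a grid spanning the search box, then refined
    by bounded scalar minimisation around the best grid point.  Curves with
    no decreasing structure (flat or increasing in N) push ``logk`` to the
    lower search bound and are flagged non-identifiable.
    """
    if isinstance(v, Mapping):
        distances = sorted(v)
        values = np.array([v[n] for n in distances], dtype=float)
    else:
        values = np.asarray(list(v), dtype=float)
        distances = list(distances)
    if len(set(distances)) < 3:
        raise ValueError("need at least 3 distinct distances")
    n = np.asarray(distances, dtype=float)
    n_shift = n - 1.0 if centered else n

    lo, hi = LOGK_BOUNDS
    grid = np.linspace(lo, hi, grid_size)
    sse = np.array([_profile_sse(g, n_shift, values)[0] for g in grid])
    j = int(np.argmin(sse))
    bracket = (grid[max(j - 1, 0)], grid[min(j + 1, grid_size - 1)])
    res = minimize_scalar(
        lambda g: _profile_sse(g, n_shift, values)[0],
        bounds=bracket,
        method="bounded",
        options={"xatol": 1e-10},
    )
    logk = float(res.x) if res.fun <= sse[j] else float(grid[j])
    _, v0 = _profile_sse(logk, n_shift, values)
    identifiable = logk > lo + 1e-3 and np.ptp(values) > 1e-12
    if not identifiable:
        logk = lo
        _, v0 = _profile_sse(logk, n_shift, values)
    return HyperbolicParams(v0, logk, converged=bool(res.success), identifiable=identifiable)


def score_choice_table(
    choices: pd.DataFrame,
    auc_norm: str = "max-possible",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score a long-format choice table into curves, indifference points and QC.

    ``choices`` columns: participant_id, distance, amount_selfish, choice
    (1 = share).  Returns ``(curves, indiff, qc)``:

    * curves: participant_id, distance, v, plus per-participant ``auc``;
    * indiff: participant_id, distance, indifference, method, b0, b1;
    * qc: participant_id, max_switches, excluded.

    Participants failing the consistency filter (any block with more than
    two switches) are flagged in ``qc`` but still scored, mirroring the
    convention that exclusion happens at analysis time.
    """
    required = {"participant_id", "distance", "amount_selfish", "choice"}
    missing = required - set(choices.columns)
    if missing:
        raise ValueError(f"choice table missing columns {sorted(missing)}")

    curve_rows, ip_rows, qc_rows = [], [], []
    for pid, ptab in choices.groupby("participant_id", sort=False):
        blocks = {}
        for dist, block in ptab.groupby("distance"):
            blocks[int(dist)] = (
                block["amount_selfish"].to_numpy(),
                block["choice"].to_numpy(),
            )
        missing_d = set(DISTANCES) - set(blocks)
        if missing_d:
            raise ValueError(
                f"participant {pid!r} missing blocks for distances {sorted(missing_d)}"
            )
        switches = {n: count_switches(*blocks[n]) for n in DISTANCES}
        excluded = max(switches.values()) > 2
        v = {}
        for n in DISTANCES:
            ip = estimate_indifference(*blocks[n], distance=n)
            v[n] = to_forgone(ip)
            ip_rows.append(
                {
                    "participant_id": pid,
                    "distance": n,
                    "indifference": ip.amount,
                    "method": ip.method,
                    "b0": ip.b0,
                    "b1": ip.b1,
                }
            )
        try:
            auc = compute_auc(v, norm=auc_norm)
        except ValueError:
            auc = np.nan
            warnings.warn(
                f"participant {pid!r}: AUC undefined under {auc_norm} normalisation"
            )
        for n in DISTANCES:
            curve_rows.append(
                {"participant_id": pid, "distance": n, "v": v[n], "auc": auc}
            )
        qc_rows.append(
            {
                "participant_id": pid,
                "max_switches": max(switches.values()),
                "excluded": excluded,
            }
        )
    return pd.DataFrame(curve_rows), pd.DataFrame(ip_rows), pd.DataFrame(qc_rows)
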