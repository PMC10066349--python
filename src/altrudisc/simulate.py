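"""Synthetic cohorts, choices, reference population and belief sliders.

Every table the pipeline consumes can be generated here, so the whole
analysis is testable without protected data.  The generative choice model
inverts the scoring model: each keep/share decision is Bernoulli with
``P(share) = logistic((v*(N) - (amount - 75)) / tau)`` where
``v*(N) = v0 / (1 + exp(logk) * (N - 1))`` is the participant's true value
curve and ``tau`` a dollar-scale temperature.  All randomness flows from a
single root seed through named substreams, so each table is reproducible
in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy.special import expit

from altrudisc.config import (
    BELIEF_TARGETS,
    CONTROL,
    DOSPERT_TRAITS,
    HEXACO_TRAITS,
    IRI_TRAITS,
    PPI_TRAITS,
    SimConfig,
)
from altrudisc.discounting import AMOUNTS, DISTANCES, SHARE_KEPT

#: baseline (mean, sd, low, high) per trait family; effects shift means in
#: SD units.  Scales: HEXACO 1-5, IRI subscales 0-28, DOSPERT 1-7 domain
#: means, psychopathy T-like scores.
_TRAIT_SCALES: dict[str, tuple[float, float, float, float]] = {
    **{t: (3.3, 0.6, 1.0, 5.0) for t in HEXACO_TRAITS},
    **{t: (14.0, 4.5, 0.0, 28.0) for t in IRI_TRAITS},
    "personal_distress": (9.0, 4.5, 0.0, 28.0),
    **{t: (3.8, 1.1, 1.0, 7.0) for t in DOSPERT_TRAITS},
    **{t: (48.0, 10.0, 0.0, 100.0) for t in PPI_TRAITS},
}

V0_TRUNCATION = (0.0, 85.0)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the root seed (stable across runs and platforms)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
    )


def _truncated_normal(rng, mean, sd, low, high, size):
    """Draw-by-rejection truncated normal; falls back to clipping for tiny sd."""
    if sd == 0:
        return np.full(size, np.clip(mean, low, high))
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < low) | (out > high)
    return np.clip(out, low, high)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant trait/demographic table plus true discounting parameters.

    Returns ``(cohort, true_params)``.  ``cohort`` has one row per
    participant: group, age, sex, education/income indicators, the six
    personality dimensions, empathy/risk/psychopathy subscales and CRT
    count.  ``true_params`` carries the generative ``(v0_true, logk_true,
    tau)`` per participant.
    """
    rng = _rng(config.seed, "cohort")
    rows, true_rows = [], []
    pid = 0
    for group in sorted(config.group_sizes):
        n = config.group_sizes[group]
        age_mu, age_sd = config.cohort_age.get(group, (40.0, 12.0))
        ages = np.round(_truncated_normal(rng, age_mu, age_sd, 19.0, 78.0, n), 1)
        female = rng.random(n) < config.female_fraction.get(group, 0.5)
        education = rng.random(n) < (0.88 if group == CONTROL else 0.73)
        income = rng.random(n) < 0.5
        crt = rng.binomial(3, 0.45, n)
        traits = {}
        for trait, (mu, sd, lo, hi) in _TRAIT_SCALES.items():
            shift = config.trait_effects.get(trait, {}).get(group, 0.0)
            traits[trait] = np.round(
                _truncated_normal(rng, mu + shift * sd, sd, lo, hi, n), 3
            )
        v0 = _truncated_normal(rng, *config.v0_dist, *V0_TRUNCATION, size=n)
        logk = rng.normal(config.logk_mean[group], config.logk_sd, n)
        for i in range(n):
            row = {
                "participant_id": f"p{pid:04d}",
                "group": group,
                "age": ages[i],
                "sex": "Female" if female[i] else "Male",
                "education": int(education[i]),
                "income": int(income[i]),
                "crt": int(crt[i]),
            }
            row.update({t: traits[t][i] for t in _TRAIT_SCALES})
            rows.append(row)
            true_rows.append(
                {
                    "participant_id": f"p{pid:04d}",
                    "group": group,
                    "v0_true": v0[i],
                    "logk_true": logk[i],
                    "tau": config.tau,
                }
            )
            pid += 1
    return pd.DataFrame(rows), pd.DataFrame(true_rows)


def generate_choice_blocks(
    true_params: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Nine binary keep/share trials per participant per distance.

    ``P(share)`` falls logistically in the forgone amount ``amount - 75``
    around the participant's true value ``v*(N)``, with temperature ``tau``.
    """
    required = {"participant_id", "v0_true", "logk_true", "tau"}
    missing = required - set(true_params.columns)
    if missing:
        raise ValueError(f"true_params missing columns {sorted(missing)}")
    rng = _rng(seed, "choices")
    n = len(true_params)
    amounts = np.array(AMOUNTS, dtype=float)
    dists = np.array(DISTANCES, dtype=float)
    v0 = true_params["v0_true"].to_numpy(float)[:, None]
    logk = true_params["logk_true"].to_numpy(float)[:, None]
    tau = true_params["tau"].to_numpy(float)[:, None, None]
    vstar = v0 / (1.0 + np.exp(logk) * (dists[None, :] - 1.0))  # (n, 7)
    forgone = amounts[None, None, :] - SHARE_KEPT  # (1, 1, 9)
    p_share = expit((vstar[:, :, None] - forgone) / tau)  # (n, 7, 9)
    draws = (rng.random(p_share.shape) < p_share).astype(int)

    pid = np.repeat(true_params["participant_id"].to_numpy(), 7 * 9)
    out = pd.DataFrame(
        {
            "participant_id": pid,
            "distance": np.tile(np.repeat(DISTANCES, 9), n),
            "amount_selfish": np.tile(AMOUNTS, 7 * n),
            "choice": draws.reshape(-1),
        }
    )
    if "group" in true_params.columns:
        out["group"] = np.repeat(true_params["group"].to_numpy(), 7 * 9)
    return out


def generate_population(config: SimConfig) -> pd.DataFrame:
    """Large reference trait population with age/sex/country strata.

    Emulates an open online personality survey: heavily skewed younger
    than the study cohort, mixed countries, six personality dimensions on
    the same 1-5 scale with no group structure.
    """
    if config.population_size < 1000:
        raise ValueError("population_size must be >= 1000 to support stratification")
    rng = _rng(config.seed, "population")
    n = config.population_size
    country = np.where(rng.random(n) < 0.55, "United States", "Other")
    age = np.round(
        _truncated_normal(rng, *config.population_age, 18.0, 90.0, n), 1
    )
    female = rng.random(n) < 0.6
    data = {
        "country": country,
        "age": age,
        "sex": np.where(female, "Female", "Male"),
    }
    for trait in HEXACO_TRAITS:
        mu, sd, lo, hi = _TRAIT_SCALES[trait]
        data[trait] = np.round(_truncated_normal(rng, mu, sd, lo, hi, n), 3)
    return pd.DataFrame(data)


def generate_belief_ratings(config: SimConfig) -> pd.DataFrame:
    """Third-person slider ratings of how much each target would forgo.

    Each rater places seven sliders (0-100) per target; the generator draws
    them from a hyperbola with target-specific ``logk`` (altruist targets
    shallower than the "average person") plus Gaussian noise, clipped to the
    slider range.
    """
    if "average person" not in config.belief_logk:
        raise ValueError('belief targets must include "average person"')
    rng = _rng(config.seed, "beliefs")
    dists = np.array(DISTANCES, dtype=float)
    rows = []
    for r in range(config.n_raters):
        rater_shift = rng.normal(0.0, config.belief_v0_sd)  # rater generosity
        for target in BELIEF_TARGETS:
            logk = config.belief_logk.get(target, config.belief_logk["average person"])
            logk = logk + rng.normal(0.0, config.belief_logk_sd)  # rater belief
            v0 = 92.0 + rater_shift
            sliders = v0 / (1.0 + np.exp(logk) * (dists - 1.0))
            sliders = sliders + rng.normal(0.0, config.belief_noise_sd, 7)
            sliders = np.clip(sliders, 0.0, 100.0)
            for d, s in zip(DISTANCES, sliders):
                rows.append(
                    {
                        "rater_id": f"r{r:04d}",
                        "target": target,
                        "distance": d,
                        "v_beliefs": round(float(s), 2),
                    }
                )
    return pd.DataFrame(rows)
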