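"""Simulation configuration.

Defaults mirror the study's shape: seven cohort groups (six altruist
populations plus community controls) at the published sample sizes, a
control discounting rate around logk = -2.8 with group-specific negative
shifts, near-ceiling undiscounted values, standardized trait shifts on
Honesty-Humility (up) and Personal Distress (down) for altruist groups,
and a large younger-skewed reference population for the matched bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: control/baseline group label used throughout.
CONTROL = "control"

#: the six altruist group labels.
ALTRUIST_GROUPS = (
    "heroic_rescuer",
    "nd_kidney_donor",
    "d_kidney_donor",
    "liver_donor",
    "marrow_donor",
    "aid_worker",
)

#: published full-sample sizes per group (trait battery cohort).
DEFAULT_GROUP_SIZES = {
    "heroic_rescuer": 27,
    "nd_kidney_donor": 132,
    "d_kidney_donor": 68,
    "liver_donor": 12,
    "marrow_donor": 55,
    "aid_worker": 53,
    CONTROL: 207,
}

#: analytic sample of the discounting task (after consistency exclusions).
CHOICE_SAMPLE_GROUP_SIZES = {
    "heroic_rescuer": 14,
    "nd_kidney_donor": 58,
    "d_kidney_donor": 57,
    "liver_donor": 11,
    "marrow_donor": 36,
    "aid_worker": 41,
    CONTROL: 58,
}

#: group shifts of mean logk relative to controls (discounting reduced in
#: most altruist groups; magnitudes follow the fitted group coefficients).
DEFAULT_LOGK_SHIFTS = {
    "heroic_rescuer": -0.72,
    "nd_kidney_donor": -1.33,
    "d_kidney_donor": -0.97,
    "liver_donor": -1.93,
    "marrow_donor": -0.63,
    "aid_worker": -1.17,
    CONTROL: 0.0,
}

#: standardized trait mean shifts for every altruist group vs controls.
DEFAULT_TRAIT_EFFECTS = {
    "honesty_humility": {g: 0.5 for g in ALTRUIST_GROUPS},
    "personal_distress": {g: -0.5 for g in ALTRUIST_GROUPS},
}

#: six-dimension personality scales (1-5 response scale).
HEXACO_TRAITS = (
    "honesty_humility",
    "emotionality",
    "extraversion",
    "agreeableness",
    "conscientiousness",
    "openness",
)

#: empathy subscales (Interpersonal Reactivity Index, summed items).
IRI_TRAITS = ("empathic_concern", "personal_distress", "perspective_taking", "fantasy")

#: domain-specific risk taking / perception subscales.
DOSPERT_TRAITS = tuple(
    f"risk_{kind}_{dom}"
    for kind in ("taking", "perception")
    for dom in ("social", "ethical", "financial", "health", "recreational")
)

#: psychopathy major subscales.
PPI_TRAITS = ("self_centered_impulsivity", "coldheartedness", "fearless_dominance")

#: the 25 predictors of the classification analysis (logk and the
#: dichotomised reflection score join the trait battery at runtime).
CLASSIFIER_PREDICTORS = (
    ("logk",)
    + HEXACO_TRAITS
    + IRI_TRAITS
    + tuple(t for t in DOSPERT_TRAITS)
    + PPI_TRAITS
    + ("crt_high",)
)

#: perception-study target list ("average person" baseline first).
BELIEF_TARGETS = ("average person",) + ALTRUIST_GROUPS


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator.

    Attributes
    ----------
    group_sizes : dict
        Participants per group label.
    trait_effects : dict
        trait -> {group -> standardized mean shift vs control}.
    v0_dist : tuple
        Mean and SD (dollars) of the true undiscounted value, truncated to
        [0, 85] — the range observable from the $75..$155 ladder.
    logk_mean : dict
        Per-group mean of true logk (control baseline plus shifts).
    logk_sd : float
        Between-participant SD of true logk.
    tau : float
        Logistic choice temperature in dollars (> 0); governs how noisy the
        keep/share decisions are around the true value threshold.
    population_size : int
        Rows of the reference trait population.
    population_age : tuple
        Mean and SD (years) of the reference-population age (younger-skewed
        relative to the cohort).
    cohort_age : dict
        group -> (mean, sd) age in years.
    female_fraction : dict
        group -> probability of Female.
    seed : int
        Root seed; every table draws from a named substream of it.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    trait_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRAIT_EFFECTS.items()}
    )
    v0_dist: tuple[float, float] = (78.0, 8.0)
    logk_mean: dict[str, float] = field(
        default_factory=lambda: {
            g: -2.8 + DEFAULT_LOGK_SHIFTS[g] for g in DEFAULT_LOGK_SHIFTS
        }
    )
    logk_sd: float = 1.5
    tau: float = 2.5
    population_size: int = 50_000
    population_age: tuple[float, float] = (28.0, 10.0)
    cohort_age: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            **{g: (44.0, 12.5) for g in ALTRUIST_GROUPS},
            CONTROL: (37.7, 9.1),
        }
    )
    female_fraction: dict[str, float] = field(
        default_factory=lambda: {
            **{g: 0.61 for g in ALTRUIST_GROUPS},
            CONTROL: 0.65,
        }
    )
    n_raters: int = 200
    belief_logk: dict[str, float] = field(
        default_factory=lambda: {
            "average person": -1.5,
            **{g: -3.0 for g in ALTRUIST_GROUPS},
        }
    )
    belief_noise_sd: float = 8.0
    belief_logk_sd: float = 0.3
    belief_v0_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} has non-positive size {n}")
        if self.tau <= 0:
            raise ValueError("choice temperature tau must be > 0")
        if self.v0_dist[1] < 0 or self.logk_sd < 0 or self.belief_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for g, f in self.female_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"female_fraction for {g!r} outside [0, 1]")
        missing = set(self.group_sizes) - set(self.logk_mean)
        if missing:
            raise ValueError(f"no logk mean configured for groups {sorted(missing)}")

    @classmethod
    def choice_sample(cls, **overrides) -> "SimConfig":
        """Configuration shaped like the discounting-task analytic sample."""
        overrides.setdefault("group_sizes", dict(CHOICE_SAMPLE_GROUP_SIZES))
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("v0_dist", "population_age"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "cohort_age" in raw:
            raw["cohort_age"] = {g: tuple(v) for g, v in raw["cohort_age"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: getattr(self, k) for k in self.__dataclass_fields__
        }
        data["v0_dist"] = list(self.v0_dist)
        data["population_age"] = list(self.population_age)
        data["cohort_age"] = {g: list(v) for g, v in self.cohort_age.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
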