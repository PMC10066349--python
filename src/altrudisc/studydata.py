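"""Published summary statistics of the altruist/control cohort.

These are the demographic values printed in the study report (percentages,
group sizes, age means/SDs); raw participant data are protected and never
shipped.  Counts are reconstructed from the printed percentages by
nearest-integer rounding and cross-checked against the printed totals
(e.g. 345 female participants of 554).
"""

from __future__ import annotations

from altrudisc.cohort import chi_square, pooled_t

#: sample sizes of the trait-battery cohort.
N_ALTRUISTS = 347
N_CONTROLS = 207

#: printed percentages.
PCT_FEMALE_ALTRUISTS = 60.81
PCT_FEMALE_CONTROLS = 64.73
PCT_COLLEGE_ALTRUISTS = 73.49
PCT_COLLEGE_CONTROLS = 87.92

#: printed age summaries (years).
AGE_ALTRUISTS = (44.06, 12.50, N_ALTRUISTS)
AGE_CONTROLS = (37.71, 9.07, N_CONTROLS)

#: printed total female count used as a rounding cross-check.
TOTAL_FEMALE = 345


def reconstruct_count(percentage: float, n: int) -> int:
    """Nearest-integer count implied by a printed percentage."""
    return int(round(percentage / 100.0 * n))


def sex_table() -> list[list[int]]:
    """Female/male counts by altruist vs control, from printed percentages."""
    fa = reconstruct_count(PCT_FEMALE_ALTRUISTS, N_ALTRUISTS)
    fc = reconstruct_count(PCT_FEMALE_CONTROLS, N_CONTROLS)
    assert fa + fc == TOTAL_FEMALE, "reconstruction fails the printed total"
    return [[fa, N_ALTRUISTS - fa], [fc, N_CONTROLS - fc]]


def education_table() -> list[list[int]]:
    """College/no-college counts by altruist vs control."""
    ca = reconstruct_count(PCT_COLLEGE_ALTRUISTS, N_ALTRUISTS)
    cc = reconstruct_count(PCT_COLLEGE_CONTROLS, N_CONTROLS)
    return [[ca, N_ALTRUISTS - ca], [cc, N_CONTROLS - cc]]


def demographic_tests() -> dict:
    """Recompute the cohort-balance statistics from the printed summaries.

    Returns the sex and education chi-squares and the age t test in one
    dictionary, each as (statistic, df, p).
    """
    return {
        "sex_chi2": chi_square(sex_table()),
        "education_chi2": chi_square(education_table()),
        "age_t": pooled_t(*AGE_ALTRUISTS[:2], AGE_ALTRUISTS[2],
                          *AGE_CONTROLS[:2], AGE_CONTROLS[2]),
    }
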