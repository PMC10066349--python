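import itertools

import pytest

from altrudisc.config import SimConfig
from altrudisc.discounting import AMOUNTS, estimate_indifference, score_choice_table
from altrudisc.simulate import generate_choice_blocks, generate_cohort


@pytest.fixture(scope="session")
def all_patterns():
    """Indifference points for every possible 9-trial response pattern."""
    return {
        bits: estimate_indifference(AMOUNTS, bits)
        for bits in itertools.product((0, 1), repeat=9)
    }


@pytest.fixture(scope="session")
def scored_cohort():
    """A study-shaped simulated cohort, scored, with QC flags."""
    cfg = SimConfig.choice_sample(seed=2)
    cohort, true_params = generate_cohort(cfg)
    choices = generate_choice_blocks(true_params, seed=2)
    curves, indiff, qc = score_choice_table(choices)
    keep = qc.loc[~qc["excluded"], "participant_id"]
    return {
        "config": cfg,
        "cohort": cohort,
        "true_params": true_params,
        "choices": choices,
        "curves": curves,
        "indiff": indiff,
        "qc": qc,
        "analytic_curves": curves[curves["participant_id"].isin(keep)],
    }
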