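import numpy as np
import pytest

import startreact as sr
from startreact import io as srio


@pytest.fixture(scope="session")
def exp1_cohort():
    """Small default-settings cohort with rendered signals (4 x 1 block)."""
    cfg = sr.exp1_config()
    return cfg, sr.generate_cohort(cfg, "exp1", 4, seed=5, n_blocks=1)


@pytest.fixture(scope="session")
def exp1_classified(exp1_cohort):
    _, sessions = exp1_cohort
    classified = sr.classify_cohort(sessions)
    gt = srio.ground_truth_frame(sessions)
    merged = classified.merge(
        gt,
        left_on=["participant_id", "trial_index"],
        right_on=["participant", "trial"],
    )
    return classified, merged


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
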