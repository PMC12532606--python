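import numpy as np
import pytest

import mscourse as m
from mscourse.cohort import SCORE_COLS


@pytest.fixture(scope="session")
def default_cfg():
    return m.default_config()


@pytest.fixture(scope="session")
def small_cohort(default_cfg):
    """250 patients over 18 months under the default generator."""
    cfg = default_cfg.replace(n_patients=250, n_months=18)
    return m.generate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def truth_meta():
    return {1: "eme", 2: "eme", 3: "eme", 4: "activity", 5: "relapse",
            6: "advanced", 7: "advanced", 8: "advanced"}


def true_score_sequences(cohort):
    """Per-patient arrays of latent composite scores."""
    return [
        g[SCORE_COLS].to_numpy(dtype=float)
        for _, g in cohort.sort_values(["patient_id", "month"]).groupby("patient_id")
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
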