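import numpy as np
import pytest

from rpt_uptake.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-participant cohort shared by read-only tests."""
    cfg = CohortConfig(n_participants=200, seed=42)
    participants, ratings, truth = generate_cohort(cfg)
    return cfg, participants, ratings, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
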