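import numpy as np
import pytest

from searchbench.matching import score_cohort, scored_table
from searchbench.synthetic import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def exp2_cohort():
    """A moderate Experiment-2-style cohort shared across integration tests."""
    cfg = GeneratorConfig.experiment2(n_participants=30, n_trials=60, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def exp2_scored(exp2_cohort):
    matches = score_cohort(
        exp2_cohort.trials, exp2_cohort.selections,
        participants=list(exp2_cohort.worker_effects.index))
    return matches, scored_table(matches, exp2_cohort.trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
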