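import numpy as np
import pytest

from cilithermo import CohortConfig, analyze_cohort, simulate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """One simulated cohort at the recorded study design (40 cells, both
    behaviors, 60 trials), with ground truth."""
    return simulate_cohort(CohortConfig(master_seed=7))


@pytest.fixture(scope="session")
def study_metrics(study_cohort):
    responses, _ = study_cohort
    return analyze_cohort(responses)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
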