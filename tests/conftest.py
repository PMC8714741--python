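import numpy as np
import pytest

from taskphenotype.scoring import cohort_metrics_frame
from taskphenotype.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-participant clean cohort shared by pipeline-level tests."""
    return simulate_cohort(SimConfig(n=40), seed=123)


@pytest.fixture(scope="session")
def small_cohort_metrics(small_cohort):
    return cohort_metrics_frame(small_cohort.records)


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
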