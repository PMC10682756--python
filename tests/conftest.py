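import numpy as np
import pytest

from hypermood.synth_cohort import CohortConfig, generate_cohort
from hypermood.synth_ema import ScheduleConfig, generate_dataset


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-sized cohort (47/48/48) with default parameters."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(
        CohortConfig(n_control=6, n_subclinical=6, n_patients=6, seed=3))


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """18 subjects, full 14-day schedule, functional features only."""
    return generate_dataset(
        small_cohort, schedule_cfg=ScheduleConfig(seed=3), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
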