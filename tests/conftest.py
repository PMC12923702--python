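import numpy as np
import pytest

from taskfc.cohort import CohortSpec, MidTiming, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """6-subject, 50-region, single-task cohort used across test modules."""
    spec = CohortSpec(
        seed=202, n_group_a=3, n_group_b=3, n_regions=50, tasks=("mid",),
        n_volumes={"mid": 150}, mid_timing=MidTiming(n_trials=27),
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(77)
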