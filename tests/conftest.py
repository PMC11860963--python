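import numpy as np
import pytest

from prlearn.cohort import CohortSpec, sample_cohort
from prlearn.task import TaskConfig, build_schedule


@pytest.fixture(scope="session")
def default_schedule():
    return build_schedule(TaskConfig())


@pytest.fixture(scope="session")
def one_block_schedule():
    return build_schedule(TaskConfig(n_blocks=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial cohort shared by read-only tests."""
    spec = CohortSpec(n_obs=6, n_con=6, seed=20240917)
    return sample_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
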