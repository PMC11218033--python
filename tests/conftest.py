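import warnings

import numpy as np
import pytest

from cogeffort import CohortConfig, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant cohort shared by the statistics tests."""
    cfg = CohortConfig(n_participants=60, seed=20240917)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
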