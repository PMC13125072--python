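import numpy as np
import pytest

from sarsmon.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """100 patients x 30 ticks with default channel structure and missingness."""
    return generate_cohort(CohortConfig(n_patients=100, records_per_patient=30, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
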