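import numpy as np
import pytest

from medinet.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (424 MS / 165 HC), shared across tests."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for structural/pipeline tests."""
    return generate_cohort(CohortConfig(n_ms=80, n_hc=40, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
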