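import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from petrushka.crosswalk import CrosswalkTable
from petrushka.synthetic import default_truth, generate_ehr_cohort, generate_rct_ipd


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def cohort(truth):
    """A mid-sized EHR cohort shared by read-only tests."""
    return generate_ehr_cohort(2000, truth, seed=11)


@pytest.fixture(scope="session")
def ipd_small(truth):
    """A small but fully connected trial network."""
    return generate_rct_ipd(20, 60, truth=truth, seed=12)


@pytest.fixture
def toy_crosswalk():
    """phq9 = k -> hdrs = 2k: strictly increasing, exactly invertible."""
    return CrosswalkTable(phq9=np.arange(28), hdrs=2.0 * np.arange(28))
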