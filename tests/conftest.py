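import numpy as np
import pytest

from dvhpredict.preprocessing import mahalanobis_filter
from dvhpredict.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_spec() -> CohortSpec:
    """Study-condition cohort: 103 cases, 7 planted feature outliers."""
    return CohortSpec(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def retained_cohort(default_cohort):
    retained, _ = mahalanobis_filter(default_cohort, alpha=0.05)
    return retained


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
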