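import warnings

import numpy as np
import pytest

from strokecausal.synthetic_cohort import CohortSpec, generate_cohort

# keep test output readable; estimator modules manage their own warnings
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_cohort_20k():
    """One moderately sized cohort from the calibrated default model."""
    spec = CohortSpec(n=20_000, seed=42)
    cohort, gt = generate_cohort(spec)
    return spec, cohort.frame, gt


@pytest.fixture(scope="session")
def randomized_cohort_20k():
    """Same structural model but coin-flip treatment (no confounding)."""
    spec = CohortSpec(n=20_000, seed=43).randomized()
    cohort, gt = generate_cohort(spec)
    return spec, cohort.frame, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
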