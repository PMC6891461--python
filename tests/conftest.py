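import warnings

import numpy as np
import pytest

from hipgait.config import CohortConfig, ClassifierConfig
from hipgait.synthetic import generate_cohort
from hipgait.features import build_feature_table


@pytest.fixture(autouse=True)
def _silence_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fewer than 2 initial")
        yield


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 5 + 5 subjects, 15 s trials (~12 strides each)."""
    return CohortConfig(n_healthy=5, n_patient=5, trial_duration=15.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, attach_reference=True)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_feature_table(small_cohort, channel_source="truth")


@pytest.fixture(scope="session")
def fast_classifier_config():
    return ClassifierConfig(n_folds=5, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
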