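import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from utiaudit.classifier import TrainingProtocol, cross_fit_probabilities, split_patient_stratified, tune_and_fit
from utiaudit.cohort import CohortConfig, generate_cohort
from utiaudit.harmonize import harmonize_table
from utiaudit.labeling import label_table

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SMALL_SEARCH = {"n_estimators": (40, 120), "max_depth": (2, 5)}


@pytest.fixture(scope="session")
def labeled_cohort():
    """Mid-size labeled synthetic cohort shared across the suite."""
    cfg = CohortConfig(n_encounters=6000, n_patients=5000, seed=42)
    return label_table(harmonize_table(generate_cohort(cfg)))


@pytest.fixture(scope="session")
def small_protocol():
    return TrainingProtocol(n_trials=2, search_space=SMALL_SEARCH, seed=5)


@pytest.fixture(scope="session")
def fitted_small(labeled_cohort, small_protocol):
    train, test = split_patient_stratified(labeled_cohort, small_protocol)
    model = tune_and_fit(train, small_protocol)
    return model, train, test


@pytest.fixture(scope="session")
def cohort_probs(labeled_cohort, fitted_small, small_protocol):
    """Cross-fitted cohort-wide probabilities for the shared cohort."""
    model, _, _ = fitted_small
    return cross_fit_probabilities(labeled_cohort, model.params, small_protocol)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
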