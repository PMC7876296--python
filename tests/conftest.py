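"""Shared fixtures: session-scoped synthetic cohorts and fitted models."""

import warnings

import numpy as np
import pytest

from carproc.adjustment import adjust, assign_bmi_group, fit_adjustment
from carproc.factors import HeywoodWarning, fit_retained_efa, label_factors
from carproc.proxies import PROXY_NAMES
from carproc.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default planted 4-factor cohort, n = 2000, fixed seed."""
    cohort, truth = generate_cohort(default_config(seed=1, n_total=2000))
    return cohort, truth


@pytest.fixture(scope="session")
def group_labels(default_cohort):
    cohort, _ = default_cohort
    return np.asarray(assign_bmi_group(cohort["bmi"].to_numpy()))


@pytest.fixture(scope="session")
def adjustment_model(default_cohort):
    cohort, _ = default_cohort
    return fit_adjustment(cohort)


@pytest.fixture(scope="session")
def adjusted_matrix(default_cohort, adjustment_model):
    cohort, _ = default_cohort
    return adjust(cohort, adjustment_model, variables=PROXY_NAMES)


@pytest.fixture(scope="session")
def factor_model(adjusted_matrix):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", HeywoodWarning)
        return fit_retained_efa(adjusted_matrix, max_factors=6)


@pytest.fixture(scope="session")
def factor_labels(factor_model):
    return label_factors(factor_model)
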