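import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromopt import (
    build_bbd,
    fit_all,
    infer_run_assignment,
    load_fixture,
)
from chromopt.doe import design_from_assignment

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_factors():
    return load_fixture("factors")


@pytest.fixture(scope="session")
def study_table():
    return load_fixture("responses")


@pytest.fixture(scope="session")
def reference_models():
    return load_fixture("models")


@pytest.fixture(scope="session")
def study_design(study_table, reference_models, study_factors):
    """The 15-run design with the run assignment recovered from the
    reported coefficient matrix."""
    assignment = infer_run_assignment(study_table, reference_models)
    return design_from_assignment(assignment, study_factors)


@pytest.fixture(scope="session")
def study_models(study_design, study_table):
    """Full quadratic models refitted to every response column."""
    return fit_all(study_design, study_table)


@pytest.fixture(scope="session")
def canonical_design(study_factors):
    return build_bbd(study_factors, n_center=3)


def random_bbd_dataset(rng, factors, n_center=3):
    """A BBD plus a response drawn from a random quadratic + noise."""
    design = build_bbd(factors, n_center=n_center)
    from chromopt.rsm import design_matrix

    beta = rng.normal(0, 2, size=10)
    X = design_matrix(design.coded_matrix())
    y = X @ beta + rng.normal(0, 0.3, size=design.n_runs)
    return design, y
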