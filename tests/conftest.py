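import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import normbench as nb
from normbench.basis import FittedBasis

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale model-true cohort spec used across the suite."""
    return nb.CohortSpec(n_rois=4, n_hc=500, n_ad=80, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return nb.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    train, test = nb.stratified_split(small_cohort, 0.8, seed=7)
    return train, test


@pytest.fixture(scope="session")
def small_pool(small_split):
    train, _ = small_split
    return train[train["diagnosis"] == "HC"]


@pytest.fixture(scope="session")
def small_models(small_pool):
    return nb.fit_cohort(small_pool)


@pytest.fixture(scope="session")
def small_zmatrix(small_models, small_split):
    _, test = small_split
    return nb.deviation_matrix(small_models, test)


@pytest.fixture(scope="session")
def gaussian_spec():
    """Identity-warp (Gaussian-residual) cohort for closed-form checks."""
    return nb.CohortSpec(n_rois=2, n_hc=1200, n_ad=0, warp_true=(0.0, 1.0),
                         seed=21)


@pytest.fixture(scope="session")
def gaussian_cohort(gaussian_spec):
    return nb.generate_cohort(gaussian_spec)


@pytest.fixture(scope="session")
def pool_basis(small_pool):
    return FittedBasis.fit(small_pool)


def make_table(n, seed=0, n_sites=1, age_range=(45.0, 82.0)):
    """Small covariate-only table for design/sampling tests."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "subject_id": [f"s{i:04d}" for i in range(n)],
        "age": rng.uniform(*age_range, size=n),
        "sex": rng.choice(["F", "M"], size=n),
        "site": rng.choice([f"site-{k:02d}" for k in range(1, n_sites + 1)],
                           size=n),
        "diagnosis": "HC",
    })
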