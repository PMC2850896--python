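import numpy as np
import pytest

from fourcomp import CohortConfig, ComponentDensities, fm_coefficients
from fourcomp.cohort import generate_cohort


@pytest.fixture(scope="session")
def densities():
    return ComponentDensities()


@pytest.fixture(scope="session")
def coeffs():
    return fm_coefficients()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture(scope="session")
def default_cohort():
    """A seeded default (n=27) cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def big_calibration_cohort():
    """Large floor-free cohort for law-of-large-numbers checks."""
    cfg = CohortConfig(seed=7, n_subjects=100_000, pfm_floor=None)
    df, meta = generate_cohort(cfg)
    return cfg, df, meta
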