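import numpy as np
import pytest

import fuzzycomm as fc


@pytest.fixture(scope="session")
def reference_cohort():
    """The six packaged reference subjects."""
    return fc.load_reference_cohort()


@pytest.fixture(scope="session")
def factor_model():
    """Packaged published loadings / score coefficients / weights."""
    return fc.load_factor_model()


@pytest.fixture(scope="session")
def published_B():
    """The published level-evidence vector for reference subject 1."""
    return np.array([0.2119, 0.2440, 0.3916, 0.1371])


@pytest.fixture
def assessor():
    return fc.FuzzyAssessor().fit()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_cohort_matrix(rng, n=12):
    """A random valid (n, 9) measurement matrix with realistic structure.

    Drawn from a mixed-severity synthetic cohort, so the indicators carry
    the dominant shared factor that real ability data shows.
    """
    spec = fc.CohortSpec(n_subjects=n, seed=int(rng.integers(2**31)))
    return fc.cohort_matrix(fc.generate(spec))
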