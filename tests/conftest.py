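import numpy as np
import pytest

from igwohealth.cohort import CohortSpec, generate_cohort, inject_missingness
from igwohealth.preprocessing import preprocess_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_spec():
    """A 400-child cohort with the same class/subgroup proportions, for speed."""
    return CohortSpec(
        n=400,
        class_counts=(300, 100),
        subgroup_counts={"obesity": 42, "lipid": 20, "respiratory": 19, "hypertension": 19},
        sex_counts=(200, 200),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    table = generate_cohort(small_spec)
    return inject_missingness(
        table, small_spec.missing_rate, np.random.default_rng(small_spec.seed + 1)
    )


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    """(X_train, y_train, X_test, y_test, feature_names, report)."""
    return preprocess_cohort(small_cohort, seed=42)


@pytest.fixture(scope="session")
def separable_toy():
    """A linearly separable 200-point binary problem."""
    rng = np.random.default_rng(0)
    n = 200
    X = rng.normal(size=(n, 4))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    X[y == 1, 0] += 2.0
    X[y == 0, 0] -= 2.0
    return X, y
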