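import numpy as np
import pandas as pd
import pytest

from pacuseq import CohortConfig, FeatureMatrix, generate_cohort


def make_matrix(X, y, prefix="R"):
    """Build a FeatureMatrix from raw arrays with synthetic row ids."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    idx = pd.Index([f"{prefix}{i:05d}" for i in range(len(X))], name="case_id")
    cols = [f"f{j}" for j in range(X.shape[1])]
    return FeatureMatrix(
        pd.DataFrame(X, index=idx, columns=cols),
        pd.Series(np.asarray(y, dtype=int), index=idx, name="prolonged"),
    )


def imbalanced_matrix(n_minority, n_majority, n_features=4, seed=0):
    """Two Gaussian blobs, minority labelled 1."""
    rng = np.random.default_rng(seed)
    Xmin = rng.normal(1.0, 1.0, size=(n_minority, n_features))
    Xmaj = rng.normal(0.0, 1.0, size=(n_majority, n_features))
    X = np.vstack([Xmin, Xmaj])
    y = np.array([1] * n_minority + [0] * n_majority)
    return make_matrix(X, y)


@pytest.fixture(scope="session")
def small_cohort():
    """400-case synthetic cohort shared by fast tests."""
    return generate_cohort(CohortConfig(n_cases=400, seed=11))


@pytest.fixture(scope="session")
def default_cohort_10k():
    """n = 10,000 cohort at generator defaults (calibration checks)."""
    return generate_cohort(CohortConfig(n_cases=10000, seed=7))
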