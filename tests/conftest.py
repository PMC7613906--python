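import numpy as np
import pytest

from psymetab.peaks import load_default_library
from psymetab.preprocessing import assemble_matrix, normalize_and_scale
from psymetab.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (70/20/53), shared across tests."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    spectra, meta, _ = default_cohort
    bm = assemble_matrix(spectra, meta)
    return normalize_and_scale(bm, "pqn", "none", center=False), meta


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def two_class_toy(n0=20, n1=15, p=12, shift=2.0, seed=0):
    """Small separable two-class matrix used by chemometrics/validation tests."""
    r = np.random.default_rng(seed)
    X0 = r.normal(size=(n0, p))
    X1 = r.normal(size=(n1, p))
    X1[:, : p // 3] += shift
    X = np.vstack([X0, X1])
    y = np.array(["a"] * n0 + ["b"] * n1)
    return X, y
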