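import numpy as np
import pytest

import synmaint as sm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_task():
    """A 4-6-3 sigmoid student-teacher task with a 50-input suite."""
    return sm.make_task(layer_sizes=(4, 6, 3), n_inputs=50, seed=7)


@pytest.fixture(scope="session")
def toy_task():
    """A 2-2-1 sigmoid task small enough for dense finite-difference Hessians."""
    return sm.make_task(layer_sizes=(2, 2, 1), n_inputs=20, seed=3)


@pytest.fixture
def aniso_quad():
    """Anisotropic positive-definite quadratic, eigenvalues log-spaced 0.1..10."""
    lam = np.geomspace(0.1, 10.0, 30)
    return sm.make_quadratic(lam, np.zeros(30), seed=42)


@pytest.fixture
def diag123():
    """Quadratic with H = diag(1, 2, 3) in the standard basis."""
    return sm.QuadraticLandscape(
        eigenvalues=np.array([1.0, 2.0, 3.0]),
        basis=np.eye(3),
        minimiser=np.zeros(3),
    )
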