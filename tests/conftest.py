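import numpy as np
import pytest

from dynglasso import SolverSettings, standardize


def random_cov(p, T, n=60, seed=0, shared_structure=True):
    """Random standardized covariance sequence from correlated Gaussian data.

    With ``shared_structure`` the time points share one mixing matrix (so
    the S_t differ only by sampling noise, the regime the smoothing
    penalty targets); otherwise each time point gets its own.
    """
    rng = np.random.default_rng(seed)
    mix = rng.standard_normal((p, p)) + 2 * np.eye(p)
    data = []
    for _ in range(T):
        if not shared_structure:
            mix = rng.standard_normal((p, p)) + 2 * np.eye(p)
        data.append(rng.standard_normal((n, p)) @ mix.T)
    return standardize(data)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cov():
    return random_cov(5, 3, n=80, seed=7)


@pytest.fixture
def tight_settings():
    return SolverSettings(tol_primal=1e-9, tol_dual=1e-9, max_iter=20000)
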