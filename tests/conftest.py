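import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_correlation(p, rng, max_abs=0.9):
    """Random symmetric matrix with unit diagonal and |off-diag| <= max_abs.

    Built from the correlation matrix of a random Gaussian sample, then
    clipped, so it is a valid input for the fusion penalty.
    """
    Z = rng.standard_normal((4 * p, p))
    rho = np.corrcoef(Z, rowvar=False)
    rho = np.clip(rho, -max_abs, max_abs)
    np.fill_diagonal(rho, 1.0)
    return rho
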