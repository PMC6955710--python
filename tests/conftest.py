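import numpy as np
import pytest

from vigilnet.mvar_pdc import VARModel, spectral_radius


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weight_matrix(rng, m, density=0.5, low=0.05, high=1.0):
    """Random nonnegative weighted directed graph, zero diagonal."""
    W = rng.uniform(low, high, size=(m, m))
    W *= rng.random((m, m)) < density
    np.fill_diagonal(W, 0.0)
    return W


def random_stable_model(rng, m, p, radius=0.8):
    """Random MVAR model shrunk to a target companion spectral radius."""
    coeffs = rng.normal(scale=0.5 / np.sqrt(m * p), size=(p, m, m))
    rho = spectral_radius(coeffs)
    if rho > 0:
        coeffs *= radius / rho * rng.uniform(0.3, 1.0)
    L = rng.normal(scale=0.3, size=(m, m))
    noise_cov = L @ L.T + np.eye(m)
    return VARModel(coeffs=coeffs, noise_cov=noise_cov, order=p)
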