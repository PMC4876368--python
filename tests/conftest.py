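import numpy as np
import pytest

from climenet import CovarianceMatrix, toy_population_covariance


@pytest.fixture(scope="session")
def toy_sigma() -> CovarianceMatrix:
    """Population covariance of the 3-node hub model (a1=0.3, a2=0.8)."""
    return CovarianceMatrix(toy_population_covariance(0.3, 0.8), n_obs=10**6)


def random_spd(M: int, seed: int, cond_max: float = 50.0) -> np.ndarray:
    """Well-conditioned random symmetric positive-definite matrix."""
    rng = np.random.default_rng(seed)
    Q = np.linalg.qr(rng.standard_normal((M, M)))[0]
    eigs = np.linspace(1.0, cond_max**0.5, M)
    return (Q * eigs) @ Q.T


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
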