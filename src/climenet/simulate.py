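"""Synthetic node time series with prescribed network structure.

The generator emulates the covariance structure of resting-state node
signals: a T x M data matrix ``Y = X + Z`` where

* rows of ``X`` are iid draws from ``N(0, Sigma_s)`` with
  ``Sigma_s = Omega^{-1} - tau^2 I`` — the spatial component carrying the
  network structure of a prescribed sparse precision matrix ``Omega``;
* columns of ``Z`` are iid AR(1) series with stationary variance ``tau^2``
  and adjacent correlation ``gamma`` — the temporal component.

Setting ``tau^2`` to half the inverse of the largest eigenvalue of
``Omega`` guarantees ``Sigma_s`` is positive definite, since the smallest
eigenvalue of ``Omega^{-1}`` is then ``2 tau^2``.  The marginal spatial
covariance of a row of ``Y`` is ``Sigma_s + tau^2 I = Omega^{-1}`` exactly,
so the spatial precision matrix of the generated data is ``Omega``.

``generate_precision`` draws the sparse ``Omega`` itself: a uniformly random
symmetric off-diagonal support at a requested sparsity level (the proportion
of nonzero off-diagonal entries), signed magnitudes uniform in a given
range, and a diagonal-dominant diagonal, rescaled so the largest diagonal
entry is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkSpec",
    "GeneratedDataset",
    "generate_precision",
    "generate_timeseries",
    "toy_three_node",
    "toy_population_covariance",
]

#: smallest eigenvalue of the drawn (standardized) precision matrix; the
#: off-diagonal block is scaled to sit this far from the positive-definite
#: boundary, making the partial correlations as strong as the sparsity
#: pattern permits
MIN_EIGENVALUE_FLOOR = 0.1
DEFAULT_MAGNITUDE_RANGE = (0.4, 0.8)
DEFAULT_GAMMA = 0.3


@dataclass
class NetworkSpec:
    """Recipe for a random sparse precision matrix.

    ``sparsity_level`` is the proportion of *nonzero* off-diagonal entries;
    the realized count is the nearest even integer to
    ``sparsity_level * M * (M - 1)`` (even, because the support is
    symmetric).
    """

    n_nodes: int
    sparsity_level: float
    seed: int
    offdiag_magnitude_range: tuple[float, float] = DEFAULT_MAGNITUDE_RANGE

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not 0 < self.sparsity_level < 1:
            raise ValueError("sparsity_level must be in (0, 1)")
        lo, hi = self.offdiag_magnitude_range
        if not 0 < lo <= hi:
            raise ValueError("magnitude range must be positive and ordered")

    @property
    def n_offdiag_nonzero(self) -> int:
        """Nearest even off-diagonal nonzero count to the requested level."""
        M = self.n_nodes
        target = self.sparsity_level * M * (M - 1)
        count = 2 * int(round(target / 2))
        if count == 0 or count >= M * (M - 1):
            attainable = count / (M * (M - 1))
            raise ValueError(
                f"sparsity level {self.sparsity_level} unattainable for M={M}; "
                f"nearest attainable proportion is {attainable:g}"
            )
        return count


@dataclass
class GeneratedDataset:
    """A synthetic (true network, time series) pair with its parameters."""

    omega_true: np.ndarray
    sigma_s: np.ndarray
    tau2: float
    gamma: float
    Y: np.ndarray
    T: int
    seed: int


def generate_precision(spec: NetworkSpec) -> np.ndarray:
    """Random symmetric positive-definite sparse precision matrix.

    Off-diagonal support is a uniformly random symmetric pattern with
    exactly ``spec.n_offdiag_nonzero`` entries; raw magnitudes are uniform
    in ``spec.offdiag_magnitude_range`` with random signs.  The matrix is
    built on the standardized scale (unit diagonal), with the off-diagonal
    block rescaled so the smallest eigenvalue equals
    ``MIN_EIGENVALUE_FLOOR``: positive definiteness is guaranteed while the
    partial correlations (``rho_ij = -omega_ij`` on this scale) stay as
    large as the sparsity pattern allows, keeping edges detectable at short
    series lengths across all sparsity levels.
    """
    rng = np.random.default_rng(spec.seed)
    M = spec.n_nodes
    n_pairs = spec.n_offdiag_nonzero // 2
    iu = np.triu_indices(M, k=1)
    chosen = rng.choice(iu[0].size, size=n_pairs, replace=False)
    lo, hi = spec.offdiag_magnitude_range
    magnitudes = rng.uniform(lo, hi, size=n_pairs)
    signs = rng.choice([-1.0, 1.0], size=n_pairs)
    B = np.zeros((M, M))
    rows, cols = iu[0][chosen], iu[1][chosen]
    B[rows, cols] = signs * magnitudes
    B[cols, rows] = B[rows, cols]
    lam_min = np.linalg.eigvalsh(B)[0]  # < 0 whenever any edge exists
    scale = (1.0 - MIN_EIGENVALUE_FLOOR) / abs(lam_min)
    return np.eye(M) + scale * B


def generate_timeseries(
    omega: np.ndarray, T: int, gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
) -> GeneratedDataset:
    """Draw a T x M time-series matrix with spatial precision ``omega`` and
    AR(1) temporal noise.

    The AR(1) component is sampled exactly at stationarity: the first row is
    ``N(0, tau^2)`` and subsequent rows follow
    ``z_t = gamma z_{t-1} + sqrt(tau^2 (1 - gamma^2)) e_t``, giving the
    temporal covariance ``tau^2 gamma^{|i-j|}``.
    """
    omega = np.asarray(omega, dtype=float)
    M = omega.shape[0]
    if T < 2:
        raise ValueError("T must be at least 2")
    if not abs(gamma) < 1:
        raise ValueError("gamma must satisfy |gamma| < 1 for stationarity")
    eigvals, eigvecs = np.linalg.eigh(omega)
    if eigvals[0] <= 0:
        raise ValueError("omega must be positive definite")
    tau2 = 0.5 / eigvals[-1]
    sigma_inv_eigs = 1.0 / eigvals
    sigma_s = (eigvecs * (sigma_inv_eigs - tau2)) @ eigvecs.T
    s_eigs = sigma_inv_eigs - tau2
    if s_eigs.min() <= 0:
        raise ValueError("spatial covariance not positive definite "
                         "(ill-conditioned omega)")
    rng = np.random.default_rng(seed)
    # X: rows iid N(0, Sigma_s) via symmetric square root
    sqrt_s = (eigvecs * np.sqrt(s_eigs)) @ eigvecs.T
    X = rng.standard_normal((T, M)) @ sqrt_s
    # Z: columns iid stationary AR(1) with variance tau2, lag-1 corr gamma
    e = rng.standard_normal((T, M))
    Z = np.empty((T, M))
    Z[0] = np.sqrt(tau2) * e[0]
    innov_sd = np.sqrt(tau2 * (1.0 - gamma**2))
    for t in range(1, T):
        Z[t] = gamma * Z[t - 1] + innov_sd * e[t]
    return GeneratedDataset(omega_true=omega, sigma_s=sigma_s, tau2=float(tau2),
                            gamma=float(gamma), Y=X + Z, T=T, seed=seed)


def toy_three_node(
    alpha1: float = 0.3, alpha2: float = 0.8, T: int = 100, seed: int = 0
) -> np.ndarray:
    """Three-node hub network: X1 = a1*X2 + e1, X3 = a2*X2 + e2.

    Nodes 1 and 3 are each driven by node 2 but share no direct link, so
    their partial correlation is exactly zero while their marginal
    correlation is ``a1 a2 / sqrt((1 + a1^2)(1 + a2^2))``.
    """
    if T < 3:
        raise ValueError("T must be at least 3")
    rng = np.random.default_rng(seed)
    x2 = rng.standard_normal(T)
    x1 = alpha1 * x2 + rng.standard_normal(T)
    x3 = alpha2 * x2 + rng.standard_normal(T)
    return np.column_stack([x1, x2, x3])


def toy_population_covariance(alpha1: float = 0.3, alpha2: float = 0.8) -> np.ndarray:
    """Population covariance of the three-node hub model."""
    return np.array([
        [1 + alpha1**2, alpha1, alpha1 * alpha2],
        [alpha1, 1.0, alpha2],
        [alpha1 * alpha2, alpha2, 1 + alpha2**2],
    ])
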