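"""Partial- and full-correlation matrices and group-level averaging.

The partial correlation between nodes i and j is their correlation after
conditioning on every other node.  Under a Gaussian model it is determined
by the precision matrix ``Omega = {w_ij}``:

    rho_ij = -w_ij / sqrt(w_ii * w_jj),      rho_ii = 1,

or in matrix form ``-D^{-1/2} Omega D^{-1/2} + 2 I`` with ``D = diag(Omega)``.
A zero partial correlation means conditional independence — the marginal
(Pearson, "full") correlation can still be large through shared neighbors,
which is exactly the distinction these matrices are built to expose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clime import PrecisionMatrixEstimate

__all__ = [
    "PartialCorrelationMatrix",
    "FullCorrelationMatrix",
    "precision_to_parcorr",
    "full_correlation",
    "group_average",
]


@dataclass
class PartialCorrelationMatrix:
    """Symmetric matrix of partial correlations with unit diagonal."""

    values: np.ndarray
    source_lambda: float | None = None
    source_is_pd: bool = True
    node_names: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class FullCorrelationMatrix:
    """Symmetric Pearson-correlation matrix with unit diagonal."""

    values: np.ndarray
    node_names: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def precision_to_parcorr(
    omega: PrecisionMatrixEstimate | np.ndarray,
) -> PartialCorrelationMatrix:
    """Partial-correlation matrix of a precision matrix.

    Computes ``-D^{-1/2} Omega D^{-1/2} + 2I`` and cross-checks it against
    the elementwise formula ``-w_ij / sqrt(w_ii w_jj)``.  For a positive
    definite input all entries lie in [-1, 1]; a non-PD input is still
    transformed (entries may then fall outside that range and are left
    unclipped — clipping would silently distort downstream effect sizes) but
    a warning is issued.
    """
    if isinstance(omega, PrecisionMatrixEstimate):
        W = omega.values
        lam: float | None = omega.lam
        is_pd = omega.is_pd
        names = omega.node_names
    else:
        W = np.asarray(omega, dtype=float)
        lam = None
        is_pd = bool(np.linalg.eigvalsh((W + W.T) / 2)[0] > 0)
        names = None
    d = np.diag(W)
    if np.any(d <= 0):
        bad = int(np.flatnonzero(d <= 0)[0])
        raise ValueError(f"precision diagonal must be positive; node {bad} has "
                         f"omega_ii = {d[bad]:g}")
    inv_sqrt = 1.0 / np.sqrt(d)
    M = W.shape[0]
    P = -(inv_sqrt[:, None] * W * inv_sqrt[None, :]) + 2 * np.eye(M)
    # elementwise formula must agree with the matrix form
    P_elem = np.empty_like(P)
    for i in range(M):
        for j in range(M):
            P_elem[i, j] = 1.0 if i == j else -W[i, j] / np.sqrt(d[i] * d[j])
    assert np.allclose(P, P_elem, atol=1e-12, rtol=0.0)
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 1.0)
    if not is_pd:
        warnings.warn("precision matrix is not positive definite; partial "
                      "correlations may fall outside [-1, 1]", stacklevel=2)
    return PartialCorrelationMatrix(P, source_lambda=lam, source_is_pd=is_pd,
                                    node_names=names)


def full_correlation(
    ts: np.ndarray, node_names: list[str] | None = None
) -> FullCorrelationMatrix:
    """Pearson ("full") correlation matrix of the columns of a T x M
    time-series matrix."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a 2-D time series with at least 3 time points")
    ptp = ts.max(axis=0) - ts.min(axis=0)
    if np.any(ptp == 0):
        bad = int(np.flatnonzero(ptp == 0)[0])
        raise ValueError(f"column {bad} is constant; correlation undefined")
    R = np.corrcoef(ts, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return FullCorrelationMatrix(R, node_names=node_names)


def group_average(
    matrices: list[np.ndarray], fisher_z: bool = False
) -> np.ndarray:
    """Entrywise mean of same-shape symmetric matrices across subjects.

    With ``fisher_z`` the off-diagonal entries are atanh-transformed before
    averaging and tanh-back-transformed after (an option for full
    correlations; plain averaging is the default).
    """
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    mats = [np.asarray(m, dtype=float) for m in matrices]
    shape = mats[0].shape
    for idx, m in enumerate(mats):
        if m.shape != shape:
            raise ValueError(f"matrix {idx} has shape {m.shape}, expected {shape}")
    stack = np.stack(mats)
    if not fisher_z:
        return stack.mean(axis=0)
    diag = np.eye(shape[0], dtype=bool)
    z = np.arctanh(np.where(diag, 0.0, stack))
    out = np.tanh(z.mean(axis=0))
    out[diag] = stack.mean(axis=0)[diag]
    return out
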