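"""Sparse precision-matrix estimation by constrained L1 minimization (CLIME).

The estimator solves, for a sample covariance matrix ``Sigma`` and tuning
parameter ``lam`` in (0, 1),

    min ||Omega||_1   subject to   |Sigma @ Omega - I|_inf <= lam,

column by column: each column ``beta`` of the initial (generally asymmetric)
estimate minimizes ``||beta||_1`` subject to
``max_k |(Sigma beta)_k - e_i[k]| <= lam``.  Each column problem is a linear
program; splitting ``beta = u - v`` with ``u, v >= 0`` gives a standard-form
LP with objective ``sum(u + v)`` and ``2M`` inequality rows.  The final
estimate symmetrizes the column solutions by keeping, for every pair (i, j),
the entry of smaller absolute value (sign preserved).

A large ``lam`` relaxes the constraint and shrinks the estimate toward the
zero matrix (for a unit-diagonal covariance, ``lam >= 1`` yields exactly
zero); ``lam -> 0`` recovers the unconstrained inverse when it exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

__all__ = [
    "CovarianceMatrix",
    "ClimeColumnSolution",
    "PrecisionMatrixEstimate",
    "sample_covariance",
    "clime_column",
    "clime_estimate",
]

#: default tolerance below which a precision entry is declared zero
#: (above LP solver tolerance, below realistic signal magnitudes)
DEFAULT_ZERO_TOL = 1e-6

_SYM_TOL = 1e-10


@dataclass
class CovarianceMatrix:
    """Empirical covariance of node time series.

    Parameters
    ----------
    values : (M, M) ndarray
        Symmetric matrix with strictly positive diagonal.
    n_obs : int
        Number of time points the covariance was computed from.
    scaled_to_correlation : bool
        Whether ``values`` has been rescaled to unit diagonal.
    node_names : list of str, optional
        Column labels carried through to outputs.
    """

    values: np.ndarray
    n_obs: int
    scaled_to_correlation: bool = False
    node_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("covariance matrix is not symmetric (tol 1e-10)")
        if np.any(np.diag(self.values) <= 0):
            raise ValueError("covariance diagonal must be strictly positive")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ClimeColumnSolution:
    """Solution of one column LP of the constrained-L1 program."""

    column_index: int
    beta: np.ndarray
    l1_norm: float
    feasible: bool
    status: str = "optimal"


@dataclass
class PrecisionMatrixEstimate:
    """Symmetrized sparse precision-matrix estimate.

    ``values`` is exactly symmetric by construction; ``zero_tol`` is the
    magnitude below which an entry is treated as a structural zero when
    counting edges.
    """

    values: np.ndarray
    lam: float
    is_pd: bool
    zero_tol: float = DEFAULT_ZERO_TOL
    feasible_columns: np.ndarray | None = field(default=None, repr=False)
    node_names: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def support(self) -> np.ndarray:
        """Boolean mask of entries with magnitude above ``zero_tol``."""
        return np.abs(self.values) > self.zero_tol

    def n_nonzero(self) -> int:
        """Number of entries above ``zero_tol`` (diagonal included,
        symmetric pairs counted twice)."""
        return int(self.support().sum())


def sample_covariance(
    ts: np.ndarray,
    to_correlation: bool = False,
    node_names: list[str] | None = None,
) -> CovarianceMatrix:
    """Empirical covariance of the columns of a T x M time-series matrix.

    Uses the unbiased divisor T - 1.  With ``to_correlation`` the matrix is
    rescaled to unit diagonal (and the flag recorded so downstream code can
    undo the scaling).

    Raises
    ------
    ValueError
        If fewer than two time points, or any column is constant.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D array (rows = time points)")
    T, M = ts.shape
    if T < 2:
        raise ValueError("need at least 2 time points to form a covariance")
    ptp = ts.max(axis=0) - ts.min(axis=0)
    if np.any(ptp == 0):
        bad = int(np.flatnonzero(ptp == 0)[0])
        raise ValueError(f"column {bad} is constant; covariance undefined for node {bad}")
    centered = ts - ts.mean(axis=0)
    cov = centered.T @ centered / (T - 1)
    cov = (cov + cov.T) / 2.0
    if to_correlation:
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        np.fill_diagonal(cov, 1.0)
    return CovarianceMatrix(cov, n_obs=T, scaled_to_correlation=to_correlation,
                            node_names=node_names)


def _column_lp_blocks(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Constraint matrix block shared by every column LP.

    Rows encode Sigma @ (u - v) - e_i <= lam and -(...) <= lam.
    """
    A = np.block([[sigma, -sigma], [-sigma, sigma]])
    c = np.ones(2 * sigma.shape[0])
    return A, c


def clime_column(sigma: CovarianceMatrix, i: int, lam: float) -> ClimeColumnSolution:
    """Solve the i-th column LP (0-based index) of the constrained-L1 program.

    Returns the minimizer of ``||beta||_1`` subject to
    ``|Sigma @ beta - e_i|_inf <= lam``.
    """
    M = sigma.n_nodes
    if not 0 <= i < M:
        raise ValueError(f"column index {i} out of range for M={M}")
    if not 0 < lam:
        raise ValueError("lam must be positive")
    S = sigma.values
    A, c = _column_lp_blocks(S)
    e = np.zeros(M)
    e[i] = 1.0
    b = np.concatenate([lam + e, lam - e])
    res = linprog(c, A_ub=A, b_ub=b, bounds=(0, None), method="highs")
    if res.status == 2:
        return ClimeColumnSolution(i, np.full(M, np.nan), np.nan, False,
                                   status=res.message)
    if res.status != 0:
        raise RuntimeError(f"LP solver failed on column {i}: {res.message}")
    beta = res.x[:M] - res.x[M:]
    return ClimeColumnSolution(i, beta, float(np.abs(beta).sum()), True)


class _JointColumnLP:
    """All M column LPs of one covariance batched into a single sparse LP.

    The column problems are independent, so they stack into one
    block-diagonal program; a single HiGHS call replaces M solver set-ups.
    Only the right-hand side depends on lam, so the constraint matrix is
    built once and reused across a tuning-parameter grid.
    """

    def __init__(self, S: np.ndarray):
        M = S.shape[0]
        self.M = M
        self.S = S
        A = np.block([[S, -S], [-S, S]])  # 2M x 2M, shared by all columns
        self.A_big = sp.block_diag([sp.csc_matrix(A)] * M, format="csc")
        self.c = np.ones(2 * M * M)
        b0 = np.zeros(2 * M * M)
        for i in range(M):
            b0[2 * M * i + i] = 1.0
            b0[2 * M * i + M + i] = -1.0
        self.b0 = b0  # b = lam + b0

    def solve(self, lam: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (Omega1 with columns beta_i, per-column feasibility)."""
        M = self.M
        res = linprog(self.c, A_ub=self.A_big, b_ub=lam + self.b0,
                      bounds=(0, None), method="highs")
        if res.status == 0:
            x = res.x.reshape(M, 2 * M)
            omega1 = (x[:, :M] - x[:, M:]).T  # column i of Omega1 = beta_i
            return omega1, np.ones(M, dtype=bool)
        # joint infeasible or failed: diagnose column by column
        omega1 = np.full((M, M), np.nan)
        feas = np.zeros(M, dtype=bool)
        cov = CovarianceMatrix(self.S, n_obs=2)
        for i in range(M):
            sol = clime_column(cov, i, lam)
            feas[i] = sol.feasible
            if sol.feasible:
                omega1[:, i] = sol.beta
        return omega1, feas


def symmetrize_min_magnitude(omega1: np.ndarray) -> np.ndarray:
    """Symmetrize by keeping, for each (i, j), the entry of smaller absolute
    value with its sign — the standard CLIME convention.

    The signed-minimum reading ``min(w_ij, w_ji)`` would systematically favor
    negative entries; this variant treats signs symmetrically.
    """
    take_transpose = np.abs(omega1.T) < np.abs(omega1)
    out = np.where(take_transpose, omega1.T, omega1)
    # exact symmetry: resolve any residual asymmetry deterministically
    return np.where(np.abs(out) <= np.abs(out.T), out, out.T)


def clime_estimate(
    sigma: CovarianceMatrix,
    lam: float,
    zero_tol: float = DEFAULT_ZERO_TOL,
    diag_perturb: float = 0.0,
) -> PrecisionMatrixEstimate:
    """Constrained-L1 precision estimate at tuning parameter ``lam``.

    Solves the M column LPs, symmetrizes by minimum magnitude, and flags
    positive definiteness via an eigenvalue check.  ``diag_perturb`` > 0 adds
    ``diag_perturb * I`` to the covariance before solving (an escape hatch
    for singular covariances; off by default).

    Raises
    ------
    RuntimeError
        If any column LP is infeasible (reported with the column indices).
    """
    if not 0 < lam:
        raise ValueError("lam must be positive")
    S = sigma.values
    if diag_perturb > 0:
        S = S + diag_perturb * np.eye(S.shape[0])
    return _estimate_from_lp(_JointColumnLP(S), lam, zero_tol, sigma.node_names)


def _estimate_from_lp(
    lp: _JointColumnLP,
    lam: float,
    zero_tol: float,
    node_names: list[str] | None = None,
) -> PrecisionMatrixEstimate:
    omega1, feas = lp.solve(lam)
    if not feas.all():
        bad = np.flatnonzero(~feas).tolist()
        raise RuntimeError(
            f"CLIME LP infeasible for columns {bad} at lam={lam:g}; "
            "increase lam or pass diag_perturb > 0"
        )
    omega = symmetrize_min_magnitude(omega1)
    eigs = np.linalg.eigvalsh(omega)
    return PrecisionMatrixEstimate(
        values=omega,
        lam=lam,
        is_pd=bool(eigs[0] > 0),
        zero_tol=zero_tol,
        feasible_columns=feas,
        node_names=node_names,
    )


def clime_path(
    sigma: CovarianceMatrix,
    lambdas: np.ndarray,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> list[PrecisionMatrixEstimate | None]:
    """Fit the constrained-L1 estimate at every value of a tuning grid.

    Reuses the shared LP structure across the grid.  Infeasible grid points
    are returned as ``None`` rather than raising (a profile can tolerate
    gaps; a single requested fit cannot).
    """
    lp = _JointColumnLP(sigma.values)
    out: list[PrecisionMatrixEstimate | None] = []
    for lam in lambdas:
        try:
            out.append(_estimate_from_lp(lp, float(lam), zero_tol, sigma.node_names))
        except RuntimeError:
            out.append(None)
    return out
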