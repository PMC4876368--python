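"""Tuning-parameter selection for the constrained-L1 precision estimator.

The sparsity of the CLIME estimate is controlled by a single tuning
parameter ``lam`` in (0, 1).  This module provides the density-based
selection rule alongside the standard comparators:

* ``Dens`` criterion — the matrix-wise L1 norm of the estimated precision
  matrix, evaluated over a decreasing grid of ``lam``.  As ``lam`` falls the
  estimate densifies and ``Dens`` rises until it plateaus near the
  unconstrained estimate.
* ``select_lambda_platu`` — the largest grid value whose ``Dens`` (and that
  of every smaller grid value) is within a relative tolerance ``epsilon`` of
  the profile maximum: the minimum-sparsity selection.
* ``select_lambda_p`` — the grid value whose ``Dens`` is closest to a target
  fraction ``p`` of the maximum: selection at a chosen density level.
* AIC / BIC on the Gaussian log-likelihood with degrees of freedom counted
  as nonzero entries, and k-fold cross-validation with negative
  log-likelihood or trace-L2 loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clime import (
    DEFAULT_ZERO_TOL,
    CovarianceMatrix,
    PrecisionMatrixEstimate,
    clime_path,
    sample_covariance,
)

__all__ = [
    "LambdaGrid",
    "DensProfile",
    "SelectionResult",
    "make_lambda_grid",
    "dens",
    "dens_profile",
    "select_lambda_platu",
    "select_lambda_p",
    "aic_bic_select",
    "kcv_select",
]

DEFAULT_GRID_MAX = 0.4
DEFAULT_GRID_MIN = 1e-10
DEFAULT_GRID_SIZE = 30
DEFAULT_EPSILON = 0.01
#: grid points to examine past the first plateau candidate before stopping
PLATEAU_LOOKAHEAD = 3


@dataclass
class LambdaGrid:
    """Strictly decreasing tuning-parameter sequence within (0, 1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("lambda grid must be a nonempty 1-D sequence")
        if np.any(v <= 0) or np.any(v >= 1):
            raise ValueError("all grid values must lie in the open interval (0, 1)")
        if np.any(np.diff(v) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")
        self.values = v

    def __len__(self) -> int:
        return self.values.size

    def __iter__(self):
        return iter(self.values)


def make_lambda_grid(
    lam_max: float = DEFAULT_GRID_MAX,
    lam_min: float = DEFAULT_GRID_MIN,
    size: int = DEFAULT_GRID_SIZE,
) -> LambdaGrid:
    """Log-spaced decreasing grid from ``lam_max`` down to ``lam_min``."""
    if not 0 < lam_min < lam_max < 1:
        raise ValueError("require 0 < lam_min < lam_max < 1")
    return LambdaGrid(np.logspace(np.log10(lam_max), np.log10(lam_min), size))


@dataclass
class DensProfile:
    """Density criterion evaluated along a tuning grid.

    ``dens`` holds one value per grid point (NaN where the LP was
    infeasible); ``estimates`` optionally retains the fitted matrices so a
    selected grid point need not be refit.
    """

    grid: LambdaGrid
    dens: np.ndarray
    epsilon: float = DEFAULT_EPSILON
    estimates: list[PrecisionMatrixEstimate | None] | None = field(
        default=None, repr=False
    )

    @property
    def dens_max(self) -> float:
        return float(np.nanmax(self.dens))

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.dens)


@dataclass
class SelectionResult:
    """Outcome of one tuning-parameter selection rule.

    ``score_trace`` holds the per-grid-point objective (density, information
    criterion, or mean CV loss); ``df`` the per-point nonzero counts where
    they were computed.
    """

    method: str
    lam_selected: float
    index: int
    p: float | None = None
    score_trace: np.ndarray | None = field(default=None, repr=False)
    df: np.ndarray | None = field(default=None, repr=False)
    warning: str | None = None


def dens(omega: PrecisionMatrixEstimate | np.ndarray) -> float:
    """Matrix-wise L1 norm: the sum of absolute values of all entries,
    diagonal included."""
    values = omega.values if isinstance(omega, PrecisionMatrixEstimate) else omega
    return float(np.abs(values).sum())


def dens_profile(
    sigma: CovarianceMatrix,
    grid: LambdaGrid | np.ndarray | None = None,
    keep_estimates: bool = True,
    stop_early: bool = False,
    epsilon: float = DEFAULT_EPSILON,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> DensProfile:
    """Evaluate the density criterion along a decreasing tuning grid.

    Fits the constrained-L1 estimate at each grid value from largest to
    smallest and records its density.  With ``stop_early`` the sweep halts
    once the density has grown by at most a relative ``epsilon`` over the
    last ``PLATEAU_LOOKAHEAD`` grid points (remaining points are recorded as
    the last value — on the plateau the criterion is stable by definition).
    """
    if grid is None:
        grid = make_lambda_grid()
    elif not isinstance(grid, LambdaGrid):
        grid = LambdaGrid(np.asarray(grid, dtype=float))
    estimates = clime_path(sigma, grid.values, zero_tol=zero_tol) if not stop_early \
        else None
    if estimates is not None:
        d = np.array([dens(e) if e is not None else np.nan for e in estimates])
        return DensProfile(grid, d, epsilon=epsilon,
                           estimates=estimates if keep_estimates else None)
    # incremental sweep with plateau-based early stopping
    from .clime import _JointColumnLP, _estimate_from_lp

    lp = _JointColumnLP(sigma.values)
    d = np.full(len(grid), np.nan)
    ests: list[PrecisionMatrixEstimate | None] = []
    for n, lam in enumerate(grid.values):
        try:
            est = _estimate_from_lp(lp, float(lam), zero_tol, sigma.node_names)
        except RuntimeError:
            est = None
        ests.append(est)
        d[n] = dens(est) if est is not None else np.nan
        k = n - PLATEAU_LOOKAHEAD
        if (est is not None and k >= 0 and np.isfinite(d[k]) and d[n] > 0
                and (d[n] - d[k]) <= epsilon * d[n]):
            d[n + 1:] = d[n]
            ests.extend([est] * (len(grid) - n - 1))
            break
    return DensProfile(grid, d, epsilon=epsilon,
                       estimates=ests if keep_estimates else None)


def select_lambda_platu(
    profile: DensProfile, epsilon: float | None = None
) -> SelectionResult:
    """Largest grid value on the density plateau.

    Returns the largest ``lam`` such that every grid value at or below it
    has density within relative tolerance ``epsilon`` of the profile
    maximum.  If no grid point qualifies (a pathological profile), the
    smallest grid value is returned with a warning.
    """
    eps = profile.epsilon if epsilon is None else epsilon
    d = profile.dens
    if np.sum(profile.valid_mask()) < 2:
        raise ValueError("plateau selection needs at least two valid profile points")
    dmax = profile.dens_max
    rel = np.abs(d - dmax) / dmax
    ok = rel <= eps  # NaN compares False: infeasible points break a plateau
    # plateau membership must hold for this and every smaller lam (later index)
    holds_tail = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.flatnonzero(holds_tail)
    if idx.size == 0:
        n = len(d) - 1
        return SelectionResult("dens_platu", float(profile.grid.values[n]), n,
                               score_trace=d,
                               warning="no plateau at tolerance; smallest lam returned")
    n = int(idx[0])
    return SelectionResult("dens_platu", float(profile.grid.values[n]), n,
                           score_trace=d)


def select_lambda_p(profile: DensProfile, p: float) -> SelectionResult:
    """Grid value whose density is closest to ``p`` times the maximum.

    Exact ties are broken toward the larger ``lam`` (the sparser estimate).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    d = profile.dens
    dist = np.abs(d - p * profile.dens_max)
    dist = np.where(np.isnan(dist), np.inf, dist)
    n = int(np.argmin(dist))  # argmin takes the first minimum: the larger lam
    return SelectionResult("dens_p", float(profile.grid.values[n]), n, p=p,
                           score_trace=d)


def _gaussian_fit_terms(
    est: PrecisionMatrixEstimate, S_val: np.ndarray
) -> tuple[float, float]:
    """(log det Omega, trace(S @ Omega)); log det is -inf when not PD."""
    sign, logdet = np.linalg.slogdet(est.values)
    if sign <= 0:
        return -np.inf, float(np.trace(S_val @ est.values))
    return float(logdet), float(np.trace(S_val @ est.values))


def aic_bic_select(
    sigma: CovarianceMatrix,
    grid: LambdaGrid | np.ndarray | None = None,
    criterion: str = "aic",
    n_obs: int | None = None,
    zero_tol: float = DEFAULT_ZERO_TOL,
    path: list[PrecisionMatrixEstimate | None] | None = None,
) -> SelectionResult:
    """Select the tuning parameter by an information criterion.

    Scores each grid value by

        T * (-log|Omega(lam)| + trace(Sigma Omega(lam))) + penalty,

    i.e. minus twice the Gaussian log-likelihood of the T observations (up
    to constants) plus penalty ``2 d(lam)`` for AIC and ``d(lam) log T``
    for BIC, where ``d(lam)`` counts entries above ``zero_tol`` (diagonal
    included, symmetric pairs twice).  Grid values whose estimate is not
    positive definite score +inf.  ``path`` may supply precomputed fits for
    the grid.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    if grid is None:
        grid = make_lambda_grid()
    elif not isinstance(grid, LambdaGrid):
        grid = LambdaGrid(np.asarray(grid, dtype=float))
    T = sigma.n_obs if n_obs is None else n_obs
    if path is None:
        path = clime_path(sigma, grid.values, zero_tol=zero_tol)
    scores = np.full(len(grid), np.inf)
    df = np.zeros(len(grid), dtype=int)
    for n, est in enumerate(path):
        if est is None:
            continue
        df[n] = est.n_nonzero()
        logdet, tr = _gaussian_fit_terms(est, sigma.values)
        if not np.isfinite(logdet):
            continue
        penalty = 2 * df[n] if criterion == "aic" else df[n] * np.log(T)
        scores[n] = T * (-logdet + tr) + penalty
    if not np.any(np.isfinite(scores)):
        raise RuntimeError("no grid value produced a positive-definite estimate")
    n = int(np.argmin(scores))
    return SelectionResult(criterion, float(grid.values[n]), n,
                           score_trace=scores, df=df)


def _fold_blocks(T: int, k: int) -> list[np.ndarray]:
    """Contiguous time blocks (respects temporal autocorrelation)."""
    edges = np.linspace(0, T, k + 1).astype(int)
    return [np.arange(edges[j], edges[j + 1]) for j in range(k)]


def kcv_select(
    ts: np.ndarray,
    grid: LambdaGrid | np.ndarray | None = None,
    loss: str = "neg_loglik",
    k: int = 5,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> SelectionResult:
    """k-fold cross-validated tuning-parameter selection.

    Time points are split into ``k`` contiguous blocks.  For each fold the
    estimator is fit on the training covariance and scored on the held-out
    block's covariance with either loss:

    * ``neg_loglik``: ``-log|Omega| + trace(S_val Omega) - M``
      (+inf when the estimate is not positive definite);
    * ``trace_l2``: ``trace(diag(S_val Omega - I)^2)``, the sum of squared
      diagonal entries of the validation residual.

    Mean loss across folds is minimized over the grid.  See
    :func:`kcv_select_both` for computing both losses in one sweep.
    """
    res = kcv_select_both(ts, grid=grid, k=k, zero_tol=zero_tol)
    if loss not in res:
        raise ValueError("loss must be 'neg_loglik' or 'trace_l2'")
    return res[loss]


def kcv_select_both(
    ts: np.ndarray,
    grid: LambdaGrid | np.ndarray | None = None,
    k: int = 5,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> dict[str, SelectionResult]:
    """Run the k-fold CV sweep once and score both losses on it.

    The fold fits are by far the dominant cost and are identical for the
    two losses, so they are shared.
    """
    ts = np.asarray(ts, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    T = ts.shape[0]
    if T < 2 * k:
        raise ValueError(f"need T >= 2k time points (T={T}, k={k})")
    if grid is None:
        grid = make_lambda_grid()
    elif not isinstance(grid, LambdaGrid):
        grid = LambdaGrid(np.asarray(grid, dtype=float))
    M = ts.shape[1]
    blocks = _fold_blocks(T, k)
    nll = np.zeros((k, len(grid)))
    tl2 = np.zeros((k, len(grid)))
    for j, val_idx in enumerate(blocks):
        train_idx = np.setdiff1d(np.arange(T), val_idx)
        S_train = sample_covariance(ts[train_idx])
        S_val = sample_covariance(ts[val_idx]).values
        path = clime_path(S_train, grid.values, zero_tol=zero_tol)
        for n, est in enumerate(path):
            if est is None:
                nll[j, n] = np.inf
                tl2[j, n] = np.inf
                continue
            logdet, tr = _gaussian_fit_terms(est, S_val)
            nll[j, n] = np.inf if not np.isfinite(logdet) else -logdet + tr - M
            resid_diag = np.diag(S_val @ est.values) - 1.0
            tl2[j, n] = float(np.sum(resid_diag**2))
    out = {}
    for name, losses in (("neg_loglik", nll), ("trace_l2", tl2)):
        mean_loss = losses.mean(axis=0)
        n = int(np.argmin(mean_loss))
        out[name] = SelectionResult(f"cv_{name}", float(grid.values[n]), n,
                                    score_trace=mean_loss)
    return out
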