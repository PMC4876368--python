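"""Simulation benchmark: selection-rule accuracy across sparsity levels.

For each (sparsity level, replicate) a random sparse precision matrix and a
matching synthetic time series are drawn; every requested selection rule
picks a tuning parameter; the resulting partial-correlation estimate is
scored against the truth by

* MSE — mean squared error over the M(M-1)/2 upper-triangle edges;
* sensitivity — fraction of true edges recovered (|rho_hat| above the zero
  tolerance where the true partial correlation is nonzero);
* specificity — fraction of true-zero edges correctly left out.

The per-run fits are shared aggressively: one constrained-L1 path over the
tuning grid serves the density-based selections and the information
criteria, and one set of fold paths serves both cross-validation losses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clime import DEFAULT_ZERO_TOL, sample_covariance
from .parcorr import precision_to_parcorr
from .simulate import DEFAULT_GAMMA, NetworkSpec, generate_precision, generate_timeseries
from .tuning import (
    LambdaGrid,
    DensProfile,
    aic_bic_select,
    dens,
    kcv_select_both,
    make_lambda_grid,
    select_lambda_p,
    select_lambda_platu,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationReport",
    "edge_mse",
    "support_metrics",
    "run_simulation_study",
    "DEFAULT_SPARSITY_LEVELS",
    "DEFAULT_METHODS",
]

#: the nine benchmark sparsity levels
DEFAULT_SPARSITY_LEVELS = (0.29, 0.36, 0.47, 0.49, 0.56, 0.76, 0.87, 0.89, 0.93)

#: all seven selection rules; "dens-p=X" selects at density fraction X
DEFAULT_METHODS = (
    "cv-loglik",
    "cv-tracel2",
    "aic",
    "bic",
    "dens-p=0.45",
    "dens-p=0.75",
    "dens-platu",
)


@dataclass
class SimulationReport:
    """Benchmark results: per-(level, method) rows, per-method averages,
    and the raw per-run records for replay."""

    rows: pd.DataFrame
    averages: pd.DataFrame
    runs: pd.DataFrame | None = field(default=None, repr=False)
    config: dict = field(default_factory=dict)


def _triu(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def edge_mse(pcorr_hat, pcorr_true) -> float:
    """Mean squared error over the upper-triangle edges of two
    partial-correlation matrices."""
    a = pcorr_hat.values if hasattr(pcorr_hat, "values") else np.asarray(pcorr_hat)
    b = pcorr_true.values if hasattr(pcorr_true, "values") else np.asarray(pcorr_true)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((_triu(a) - _triu(b)) ** 2))


def support_metrics(
    pcorr_hat, pcorr_true, zero_tol: float = DEFAULT_ZERO_TOL
) -> tuple[float, float]:
    """(sensitivity, specificity) of edge detection over upper-triangle
    edges.

    An edge is "detected" when the estimated magnitude exceeds ``zero_tol``;
    a true edge is one whose true value is exactly nonzero.  Either rate is
    NaN when its denominator is empty (no true edges, or no true zeros).
    """
    a = pcorr_hat.values if hasattr(pcorr_hat, "values") else np.asarray(pcorr_hat)
    b = pcorr_true.values if hasattr(pcorr_true, "values") else np.asarray(pcorr_true)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    est_edge = np.abs(_triu(a)) > zero_tol
    true_edge = _triu(b) != 0
    n_true = int(true_edge.sum())
    n_zero = int((~true_edge).sum())
    sens = float(est_edge[true_edge].sum() / n_true) if n_true else float("nan")
    spec = float((~est_edge[~true_edge]).sum() / n_zero) if n_zero else float("nan")
    return sens, spec


def _parse_method(method: str) -> tuple[str, float | None]:
    if method.startswith("dens-p="):
        return "dens-p", float(method.split("=", 1)[1])
    return method, None


def run_simulation_study(
    levels=DEFAULT_SPARSITY_LEVELS,
    n_runs: int = 100,
    T: int = 50,
    M: int = 10,
    methods=DEFAULT_METHODS,
    seed: int = 0,
    gamma: float = DEFAULT_GAMMA,
    grid: LambdaGrid | None = None,
    zero_tol: float = DEFAULT_ZERO_TOL,
    epsilon: float = 0.01,
) -> SimulationReport:
    """Run the full benchmark and aggregate the three accuracy metrics.

    Per (level, run): draw a sparse precision matrix and a T x M series,
    form the sample covariance, fit one constrained-L1 path over the grid,
    then let each selection rule pick its grid point and score the implied
    partial-correlation estimate against the truth.  Replicate seeds are
    spawned deterministically from ``seed``, so the full report is
    reproducible and each run can be replayed in isolation.

    A method that fails on a run contributes NaN metrics for that run (the
    run is kept, not dropped).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    methods = list(methods)
    parsed = [_parse_method(m) for m in methods]
    if grid is None:
        grid = make_lambda_grid()
    need_cv = any(name.startswith("cv-") for name, _ in parsed)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(levels) * n_runs)
    records = []
    for li, level in enumerate(levels):
        for run in range(n_runs):
            ss = children[li * n_runs + run]
            s_omega, s_ts = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
            omega_true = generate_precision(
                NetworkSpec(n_nodes=M, sparsity_level=level, seed=s_omega)
            )
            ds = generate_timeseries(omega_true, T=T, gamma=gamma, seed=s_ts)
            pcorr_true = precision_to_parcorr(omega_true)
            sigma = sample_covariance(ds.Y)
            path = None
            profile = None
            cv_results = None
            try:
                from .clime import clime_path

                path = clime_path(sigma, grid.values, zero_tol=zero_tol)
                d = np.array([dens(e) if e is not None else np.nan for e in path])
                profile = DensProfile(grid, d, epsilon=epsilon, estimates=path)
            except Exception:  # pragma: no cover - path failure is per-method NaN
                pass
            if need_cv:
                try:
                    cv_results = kcv_select_both(ds.Y, grid=grid, zero_tol=zero_tol)
                except Exception:
                    cv_results = None
            for method, (name, p) in zip(methods, parsed):
                rec = {"level": level, "run": run, "method": method,
                       "lam": np.nan, "mse": np.nan,
                       "sensitivity": np.nan, "specificity": np.nan}
                try:
                    if name == "dens-platu":
                        sel = select_lambda_platu(profile)
                    elif name == "dens-p":
                        sel = select_lambda_p(profile, p)
                    elif name == "aic" or name == "bic":
                        sel = aic_bic_select(sigma, grid, criterion=name,
                                             zero_tol=zero_tol, path=path)
                    elif name == "cv-loglik":
                        sel = cv_results["neg_loglik"]
                    elif name == "cv-tracel2":
                        sel = cv_results["trace_l2"]
                    else:
                        raise ValueError(f"unknown method {method!r}")
                    est = path[sel.index]
                    if est is None:
                        raise RuntimeError("selected grid point was infeasible")
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pcorr_hat = precision_to_parcorr(est)
                    sens, spec = support_metrics(pcorr_hat, pcorr_true, zero_tol)
                    rec.update(lam=sel.lam_selected,
                               mse=edge_mse(pcorr_hat, pcorr_true),
                               sensitivity=sens, specificity=spec)
                except Exception as exc:
                    logger.warning("method %s failed on level %.2f run %d: %s",
                                   method, level, run, exc)
                records.append(rec)
    runs_df = pd.DataFrame.from_records(records)
    per_level = (runs_df.groupby(["method", "level"], sort=False)
                 [["mse", "sensitivity", "specificity"]].mean().reset_index())
    averages = (per_level.groupby("method", sort=False)
                [["mse", "sensitivity", "specificity"]].mean().reset_index())
    averages["avg_sens_spec"] = (averages["sensitivity"] + averages["specificity"]) / 2
    config = {"levels": list(levels), "n_runs": n_runs, "T": T, "M": M,
              "methods": methods, "seed": seed, "gamma": gamma,
              "grid": grid.values.tolist(), "zero_tol": zero_tol,
              "epsilon": epsilon}
    return SimulationReport(rows=per_level, averages=averages, runs=runs_df,
                            config=config)
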