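"""Evaluation statistics for theta estimators.

The comparison statistic throughout is the normalized mean squared error
(nMSE), the MSE divided by the true theta, which puts estimation error on a
comparable scale across mutation rates (for an unbiased estimator at free
recombination it equals ``1 / h_n`` independently of theta).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .sfs import SFSDataset
from .simulate import (
    CoalescentParams,
    simulate_kingman_sfs,
    simulate_recomb_sfs,
    simulate_unlinked_sfs,
)

__all__ = ["nmse", "bias", "subset_nmse", "EvaluationGrid", "compare_estimators"]


def nmse(estimates: np.ndarray, theta_true: float) -> float:
    """Normalized MSE: ``mean((theta_hat - theta)^2) / theta``."""
    if theta_true <= 0:
        raise ValueError("nMSE requires theta_true > 0")
    est = np.asarray(estimates, dtype=float)
    return float(np.mean((est - theta_true) ** 2) / theta_true)


def bias(estimates: np.ndarray, theta_true: float) -> float:
    """Mean estimation error ``mean(theta_hat) - theta``."""
    return float(np.mean(np.asarray(estimates, dtype=float)) - theta_true)


def subset_nmse(
    estimates: np.ndarray, thetas: np.ndarray, boundaries: np.ndarray
) -> np.ndarray:
    """Per-subset empirical nMSE over theta bins ``(t_{k-1}, t_k]``.

    Each sample contributes ``(theta_hat_i - theta_i)^2 / theta_i``; samples
    are grouped by which bin of ``boundaries`` their true theta falls in.
    Empty bins yield ``nan``.
    """
    est = np.ravel(np.asarray(estimates, dtype=float))
    th = np.asarray(thetas, dtype=float)
    contrib = (est - th) ** 2 / th
    k = np.searchsorted(boundaries, th, side="left") - 1
    n_bins = len(boundaries) - 1
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = k == b
        if mask.any():
            out[b] = contrib[mask].mean()
    return out


@dataclass(frozen=True)
class EvaluationGrid:
    """A grid of (theta, rho) evaluation cells.

    ``rho = inf`` cells use the unlinked sampler, ``rho = 0`` the native
    Kingman sampler, anything else the msprime adapter over ``seq_length``
    sites.
    """

    theta_values: Sequence[float]
    rho_values: Sequence[float]
    reps: int
    n: int
    seq_length: float = 100_000.0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("need reps >= 1")
        if len(self.theta_values) == 0 or len(self.rho_values) == 0:
            raise ValueError("grids must be non-empty")


def _simulate_cell(
    n: int, theta: float, rho: float, reps: int, seq_length: float,
    rng: np.random.Generator,
) -> SFSDataset:
    params = CoalescentParams(n, theta, 0.0 if np.isinf(rho) else rho, seq_length)
    if rho == 0:
        return simulate_kingman_sfs(params, reps, rng=rng)
    if np.isinf(rho):
        return simulate_unlinked_sfs(params, reps, rng=rng)
    return simulate_recomb_sfs(params, reps, rng=rng)


def compare_estimators(
    grid: EvaluationGrid,
    estimators: Sequence[Callable[[np.ndarray], np.ndarray]],
    seed: int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo comparison table over a (theta, rho) grid.

    Each cell simulates ``grid.reps`` fresh SFS replicates (never reusing
    training data) and evaluates every estimator on the same replicates, so
    per-cell differences between estimators are paired.  Columns report nMSE,
    bias and variance with Monte-Carlo standard errors.

    Estimators are callables mapping an SFS replicate matrix to a vector of
    estimates, exposing a ``name`` attribute and built for matching ``n``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for theta in grid.theta_values:
        for rho in grid.rho_values:
            ds = _simulate_cell(grid.n, float(theta), float(rho), grid.reps,
                                grid.seq_length, rng)
            for est in estimators:
                values = np.asarray(est(ds.sfs), dtype=float)
                if values.shape != (grid.reps,):
                    raise ValueError(
                        f"estimator {getattr(est, 'name', est)!r} returned shape "
                        f"{values.shape}, expected ({grid.reps},)"
                    )
                sq = (values - theta) ** 2
                b = values.mean() - theta
                var = values.var()  # ddof=0 so that mse == var + bias^2 exactly
                rows.append(
                    {
                        "estimator": getattr(est, "name", repr(est)),
                        "theta": theta,
                        "rho": rho,
                        "reps": grid.reps,
                        "nmse": sq.mean() / theta,
                        "nmse_se": sq.std(ddof=1) / np.sqrt(grid.reps) / theta,
                        "bias": b,
                        "bias_se": values.std(ddof=1) / np.sqrt(grid.reps),
                        "variance": var,
                        "mse": sq.mean(),
                    }
                )
    return pd.DataFrame(rows)
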