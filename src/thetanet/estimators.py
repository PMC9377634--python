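"""Model-based linear estimators of the scaled mutation rate theta.

All estimators here are linear in the unfolded site frequency spectrum,
``theta_hat = a' S``, and differ in the choice of coefficient vector ``a``:

* Watterson's estimator uses equal coefficients ``1 / h_n`` and is unbiased
  under any recombination rate; it is the minimum-variance unbiased estimator
  in the unlinked-loci (free recombination) limit.
* Fu's estimator is the best linear unbiased estimator (BLUE) at zero
  recombination, built from the second-moment model of the SFS:
  ``Cov(S) = theta * D_alpha + theta^2 * Sigma`` with ``E[S] = theta * alpha``,
  ``alpha_i = 1/i``.
* The Futschik–Gach estimator drops unbiasedness and minimizes the mean
  squared error among all linear estimators under the same model.

The optimal coefficients depend on the unknown true theta, so practical
estimation iterates a fixed point: plug the current estimate into the
coefficient formula and re-estimate until the value stabilizes
(:func:`iterate_estimator`).  Iteration from Watterson's estimate typically
converges in a handful of steps.

Implementation note: ``(D_alpha + theta * Sigma)^{-1} x`` is evaluated for many
theta values through a one-time symmetric eigendecomposition of
``D^{-1/2} Sigma D^{-1/2}``, which makes per-theta coefficients O(n^2) and lets
the iterative estimators run vectorized over whole replicate matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .sfs import SiteFrequencySpectrum

__all__ = [
    "harmonic_sums",
    "beta_n",
    "fu_sigma",
    "FuModel",
    "LinearEstimator",
    "IterationConfig",
    "watterson",
    "watterson_variance",
    "fu_blue_coefficients",
    "futschik_mmse_coefficients",
    "futschik_segregating_coefficient",
    "iterate_estimator",
    "iterate_batch",
    "WattersonEstimator",
    "IterativeEstimator",
]

Family = Literal["fu", "futschik", "futschik_segregating"]


def _harmonic_table(m: int) -> np.ndarray:
    """``h[k] = sum_{j=1}^{k-1} 1/j`` for k = 0..m (empty sum for k <= 1)."""
    h = np.zeros(m + 1)
    if m >= 2:
        h[2:] = np.cumsum(1.0 / np.arange(1, m))
    return h


def harmonic_sums(n: int) -> tuple[float, float]:
    """Return ``(h_n, g_n)`` with ``h_n = sum_{i<n} 1/i``, ``g_n = sum_{i<n} 1/i^2``.

    Note the convention: the sums run over ``i = 1..n-1``, so ``h_2 = 1`` and
    ``h_1 = 0``.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def beta_n(n: int, i: int) -> float:
    """Second-moment helper ``beta_n(i)`` of the zero-recombination SFS model.

    ``beta_n(i) = 2n (h_{n+1} - h_i) / ((n-i+1)(n-i)) - 2/(n-i)`` with the
    partial-sum harmonic convention of :func:`harmonic_sums`.
    Defined for ``1 <= i <= n - 1``.
    """
    if not 1 <= i <= n - 1:
        raise ValueError(f"beta_n index must satisfy 1 <= i <= n-1, got i={i}, n={n}")
    h = _harmonic_table(n + 1)
    return 2.0 * n * (h[n + 1] - h[i]) / ((n - i + 1) * (n - i)) - 2.0 / (n - i)


def fu_sigma(n: int) -> "FuModel":
    """Build the per-``n`` second-moment model of the SFS at zero recombination.

    Returns a :class:`FuModel` bundling ``alpha``, ``h_n``, ``g_n`` and the
    symmetric matrix ``Sigma`` such that ``Cov(S) = theta D_alpha +
    theta^2 Sigma`` under the Kingman coalescent with infinitely-many-sites
    mutation.
    """
    return FuModel(n)


class FuModel:
    """Second-moment theory of the SFS at rho = 0 for sample size ``n``.

    Attributes
    ----------
    alpha : ``alpha_i = 1/i`` (the expected SFS is ``theta * alpha``).
    sigma : symmetric matrix with ``Cov(S) = theta D_alpha + theta^2 Sigma``.
    h, g : partial harmonic sums ``h_n``, ``g_n``.
    """

    def __init__(self, n: int):
        if n < 2:
            raise ValueError(f"need n >= 2, got {n}")
        self.n = n
        i = np.arange(1, n)
        self.alpha = 1.0 / i
        self.h, self.g = harmonic_sums(n)
        self.sigma = self._build_sigma(n)
        # Eigendecomposition of B = D^{-1/2} Sigma D^{-1/2}; then
        # (D + t*Sigma)^{-1} x = D^{-1/2} Q diag(1/(1+t*lam)) Q' D^{-1/2} x.
        d_isqrt = np.sqrt(i.astype(float))  # 1/sqrt(alpha_i)
        b = self.sigma * d_isqrt[:, None] * d_isqrt[None, :]
        lam, q = np.linalg.eigh(0.5 * (b + b.T))
        self._d_isqrt = d_isqrt
        self._lam = lam
        self._q = q
        # cached pieces for resolvent-vector products against alpha
        self._qt_dis_alpha = q.T @ (d_isqrt * self.alpha)

    @staticmethod
    def _build_sigma(n: int) -> np.ndarray:
        h = _harmonic_table(n + 1)
        beta = np.zeros(n + 1)
        for i in range(1, n):
            beta[i] = (
                2.0 * n * (h[n + 1] - h[i]) / ((n - i + 1) * (n - i))
                - 2.0 / (n - i)
            )
        sigma = np.zeros((n - 1, n - 1))
        for i in range(1, n):
            if 2 * i < n:
                sigma[i - 1, i - 1] = beta[i + 1]
            elif 2 * i == n:
                sigma[i - 1, i - 1] = 2.0 * (h[n] - h[i]) / (n - i) - 1.0 / i**2
            else:
                sigma[i - 1, i - 1] = beta[i] - 1.0 / i**2
        for i in range(1, n):
            for j in range(1, i):  # i > j; fill symmetric pair
                if i + j < n:
                    val = (beta[i + 1] - beta[i]) / 2.0
                elif i + j == n:
                    val = (
                        (h[n] - h[i]) / (n - i)
                        + (h[n] - h[j]) / (n - j)
                        - (beta[i] + beta[j + 1]) / 2.0
                        - 1.0 / (i * j)
                    )
                else:
                    val = (beta[j] - beta[j + 1]) / 2.0 - 1.0 / (i * j)
                sigma[i - 1, j - 1] = sigma[j - 1, i - 1] = val
        return sigma

    def covariance(self, theta: float) -> np.ndarray:
        """Model covariance ``theta D_alpha + theta^2 Sigma`` of the SFS."""
        return theta * np.diag(self.alpha) + theta**2 * self.sigma

    def _resolvent_alpha(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``y(t) = (D + t Sigma)^{-1} alpha`` and ``alpha' y(t)``.

        ``theta`` may be a scalar or a vector; ``y`` has shape
        ``(len(theta), n-1)``.
        """
        t = np.atleast_1d(np.asarray(theta, dtype=float))
        denom = 1.0 + t[:, None] * self._lam[None, :]
        w = self._qt_dis_alpha[None, :] / denom
        y = (w @ self._q.T) * self._d_isqrt[None, :]
        return y, y @ self.alpha


@dataclass(frozen=True)
class LinearEstimator:
    """A linear SFS estimator ``theta_hat = coeffs' S``."""

    coeffs: np.ndarray
    family: str

    def estimate(self, sfs) -> float | np.ndarray:
        arr = sfs.counts if isinstance(sfs, SiteFrequencySpectrum) else np.asarray(sfs)
        return arr @ self.coeffs


@dataclass(frozen=True)
class IterationConfig:
    """Fixed-point iteration settings: start at Watterson, stop at ``tol``."""

    tol: float = 1e-3
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("need tol > 0 and max_iter >= 1")


def watterson(sfs) -> float | np.ndarray:
    """Watterson's estimator ``M / h_n`` (``M`` = total segregating sites).

    Accepts a :class:`SiteFrequencySpectrum`, a length ``n-1`` vector, or a
    replicate matrix (rows = replicates), returning a vector in the last case.
    """
    if isinstance(sfs, SiteFrequencySpectrum):
        h, _ = harmonic_sums(sfs.n)
        return float(sfs.counts.sum() / h)
    arr = np.asarray(sfs)
    h, _ = harmonic_sums(arr.shape[-1] + 1)
    return arr.sum(axis=-1) / h


def watterson_variance(theta: float, n: int, regime: str = "linked") -> float:
    """Closed-form variance of Watterson's estimator.

    ``regime="linked"`` (no recombination): ``theta/h_n + theta^2 g_n/h_n^2``.
    ``regime="unlinked"`` (free recombination): ``theta/h_n``.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    h, g = harmonic_sums(n)
    if regime == "linked":
        return theta / h + theta**2 * g / h**2
    if regime == "unlinked":
        return theta / h
    raise ValueError(f"unknown regime {regime!r}; use 'linked' or 'unlinked'")


def fu_blue_coefficients(model: FuModel, theta: float) -> LinearEstimator:
    """Fu's BLUE coefficients at a given theta.

    ``a(theta)' = alpha' (D_alpha + theta Sigma)^{-1} /
    (alpha' (D_alpha + theta Sigma)^{-1} alpha)``; unbiased (``a' alpha = 1``)
    and variance-minimal at zero recombination.  At ``theta = 0`` this reduces
    to Watterson's equal weights ``1/h_n``.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    y, norm = model._resolvent_alpha(theta)
    a = y[0] / norm[0]
    return LinearEstimator(a, "fu")


def _blue_batch(model: FuModel, theta: np.ndarray) -> np.ndarray:
    y, norm = model._resolvent_alpha(theta)
    return y / norm[:, None]


def futschik_mmse_coefficients(model: FuModel, theta: float) -> LinearEstimator:
    """Futschik–Gach minimum-MSE coefficients at a given theta.

    ``a' = alpha' (D_alpha/theta + Sigma + alpha alpha')^{-1}``, equivalently
    ``a = theta (D + theta Sigma)^{-1} alpha / (1 + theta alpha' (D + theta
    Sigma)^{-1} alpha)`` by the Sherman–Morrison identity.  Biased (shrinks
    toward zero) but minimizes ``E[(a'S - theta)^2]`` at rho = 0.
    """
    if theta <= 0:
        raise ValueError("Futschik coefficients require theta > 0")
    return LinearEstimator(_mmse_batch(model, np.array([theta]))[0], "futschik")


def _mmse_batch(model: FuModel, theta: np.ndarray) -> np.ndarray:
    y, norm = model._resolvent_alpha(theta)
    t = np.atleast_1d(np.asarray(theta, dtype=float))
    return t[:, None] * y / (1.0 + t * norm)[:, None]


def futschik_segregating_coefficient(model: FuModel, theta: float) -> float:
    """MSE-optimal multiplier for the segregating-sites count at rho = 0.

    The estimator ``c * M`` with ``c = theta h_n / (h_n + theta g_n +
    theta h_n^2)`` minimizes ``E[(c M - theta)^2]`` under the linked model;
    ``c`` always shrinks below Watterson's ``1/h_n``.
    """
    if theta <= 0:
        raise ValueError("requires theta > 0")
    h, g = model.h, model.g
    return theta * h / (h + theta * g + theta * h**2)


def _coeff_batch(model: FuModel, family: str, theta: np.ndarray) -> np.ndarray:
    if family == "fu":
        return _blue_batch(model, theta)
    if family == "futschik":
        return _mmse_batch(model, theta)
    if family == "futschik_segregating":
        t = np.atleast_1d(theta)
        c = t * model.h / (model.h + t * model.g + t * model.h**2)
        return np.repeat(c[:, None], model.n - 1, axis=1)
    raise ValueError(f"unknown estimator family {family!r}")


def iterate_batch(
    sfs_matrix: np.ndarray,
    family: Family = "fu",
    config: IterationConfig = IterationConfig(),
    model: FuModel | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fixed-point iteration over a matrix of SFS replicates.

    Starting from Watterson's estimate per row, repeatedly re-evaluates the
    theta-dependent optimal coefficients at the current estimate until
    successive values differ by less than ``config.tol``.  Negative iterates
    are clamped to zero; rows with no segregating sites return zero
    immediately.

    Returns ``(theta_hat, n_iter, converged)`` arrays, where ``n_iter`` counts
    coefficient updates including the one at which convergence is detected.
    """
    arr = np.atleast_2d(np.asarray(sfs_matrix, dtype=float))
    n = arr.shape[1] + 1
    if model is None:
        model = FuModel(n)
    elif model.n != n:
        raise ValueError(f"model built for n={model.n}, SFS implies n={n}")
    theta = np.asarray(watterson(arr), dtype=float)
    n_iter = np.zeros(len(arr), dtype=int)
    converged = theta == 0.0  # zero SFS: 0 is the fixed point
    active = ~converged
    for _ in range(config.max_iter):
        if not active.any():
            break
        t_act = theta[active]
        if family == "futschik_segregating":
            c = t_act * model.h / (model.h + t_act * model.g + t_act * model.h**2)
            new = c * arr[active].sum(axis=1)
        else:
            coeffs = _coeff_batch(model, family, t_act)
            new = np.einsum("ij,ij->i", coeffs, arr[active])
        new = np.maximum(new, 0.0)
        n_iter[active] += 1
        done = np.abs(new - t_act) < config.tol
        theta[active] = new
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False
    return theta, n_iter, converged


def iterate_estimator(
    sfs,
    family: Family = "fu",
    config: IterationConfig = IterationConfig(),
    model: FuModel | None = None,
) -> tuple[float, int, bool]:
    """Iterative, theta-free version of a theta-dependent optimal estimator.

    ``family="fu"`` yields the iterative-variance estimator (theta_ItV),
    ``family="futschik"`` the iterative minimum-MSE estimator (theta_ItMSE),
    ``family="futschik_segregating"`` the segregating-sites variant.

    Returns ``(theta_hat, n_iter, converged)``.
    """
    arr = sfs.counts if isinstance(sfs, SiteFrequencySpectrum) else np.asarray(sfs)
    theta, n_iter, conv = iterate_batch(arr[None, :], family, config, model)
    return float(theta[0]), int(n_iter[0]), bool(conv[0])


class WattersonEstimator:
    """Callable wrapper with a name, for evaluation tables and scans."""

    name = "watterson"

    def __init__(self, n: int):
        self.n = n
        self.h, _ = harmonic_sums(n)

    def __call__(self, sfs_matrix: np.ndarray) -> np.ndarray:
        arr = np.atleast_2d(np.asarray(sfs_matrix))
        if arr.shape[1] != self.n - 1:
            raise ValueError(f"expected {self.n - 1} SFS columns, got {arr.shape[1]}")
        return arr.sum(axis=1) / self.h


class IterativeEstimator:
    """Callable wrapper around :func:`iterate_batch` for a fixed family."""

    def __init__(self, n: int, family: Family = "fu",
                 config: IterationConfig = IterationConfig()):
        self.n = n
        self.family = family
        self.config = config
        self.model = FuModel(n)
        self.name = {"fu": "fu_iterative", "futschik": "futschik_iterative",
                     "futschik_segregating": "futschik_segregating_iterative"}[family]

    def __call__(self, sfs_matrix: np.ndarray) -> np.ndarray:
        arr = np.atleast_2d(np.asarray(sfs_matrix))
        if arr.shape[1] != self.n - 1:
            raise ValueError(f"expected {self.n - 1} SFS columns, got {arr.shape[1]}")
        theta, _, _ = iterate_batch(arr, self.family, self.config, self.model)
        return theta
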