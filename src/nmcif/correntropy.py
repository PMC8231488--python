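"""Correntropy kernel, whitened augmented regression, and the IRLS fixed point.

The robust update of the filter maximizes the correntropy between a stacked,
whitened regression and the state.  Prior mean and pseudo-observation are
stacked as

    [x_bar; g(y)] = [I; I] x + delta,     delta ~ (0, blockdiag(chi_bar^-1, V^-1)),

and whitened by a factor S with S.T @ S = blockdiag(chi_bar, V), giving

    D = M x + e,     D = S [x_bar; g(y)],  M = S [I; I],  cov(e) = I.

The cost J(x) = (1/2n) sum_i G_sigma(d_i - m_i x) with the Gaussian kernel
G_sigma(e) = exp(-e^2 / 2 sigma^2) is maximized by iteratively reweighted least
squares: each pass solves the normal equations with per-row kernel weights
evaluated at the previous iterate (a half-quadratic majorize-minimize step, so
the cost never decreases).  As sigma -> infinity all weights become 1 and the
solution is the ordinary information-filter update in a single pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._linalg import NotPositiveDefiniteError, spd_sqrt

__all__ = [
    "KernelSpec",
    "AugmentedSystem",
    "FixedPointSettings",
    "FixedPointResult",
    "FilterDivergenceError",
    "gaussian_kernel",
    "influence_phi",
    "build_augmented_system",
    "correntropy_cost",
    "fixed_point_solve",
    "solve_augmented",
    "gain_form_update",
]


class FilterDivergenceError(RuntimeError):
    """Fixed-point iteration diverged (typically: kernel bandwidth too small)."""


def _validate_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if not sigma > 0.0:
        raise ValueError(f"kernel bandwidth must be positive, got {sigma}")
    return sigma


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian correntropy kernel; ``sigma = inf`` is the all-weights-one sentinel."""

    sigma: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", _validate_sigma(self.sigma))


@dataclass(frozen=True)
class FixedPointSettings:
    """Stopping rule for the IRLS fixed point.

    ``omega`` is the relative-change tolerance on the iterate, ``max_iter`` the
    preset iteration cap, and ``min_sigma_guard`` the bandwidth below which a
    divergence warning is emitted before iterating.  ``weight_tol`` is the
    weight-stationarity tolerance: when no kernel weight moves by more than
    this between iterates, the next solve would reproduce the current iterate
    exactly, so the iteration has converged.
    """

    omega: float = 1e-6
    max_iter: int = 50
    min_sigma_guard: float = 0.1
    weight_tol: float = 1e-12

    def __post_init__(self) -> None:
        if not self.omega > 0.0:
            raise ValueError("omega must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class AugmentedSystem:
    """Whitened stacked regression D = M x + e with identity noise covariance."""

    D: np.ndarray
    M: np.ndarray
    S_chi: np.ndarray
    S_V: np.ndarray

    @property
    def n(self) -> int:
        return self.M.shape[1]


@dataclass
class FixedPointResult:
    x_hat: np.ndarray
    iterations: int
    weights_chi: np.ndarray
    weights_V: np.ndarray
    converged: bool

    @property
    def weights(self) -> np.ndarray:
        return np.concatenate([self.weights_chi, self.weights_V])


def gaussian_kernel(e: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """G_sigma(e) = exp(-e^2 / (2 sigma^2)); identically 1 at the inf sentinel."""
    sigma = _validate_sigma(sigma)
    e = np.asarray(e, dtype=float)
    if np.isinf(sigma):
        out = np.ones_like(e)
    else:
        out = np.exp(-np.square(e) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


def influence_phi(e: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """Influence function phi(e) = e * G_sigma(e).

    Odd and bounded on the whole real line: |phi| peaks at e = +-sigma with
    value sigma * exp(-1/2) and redescends to zero, which is what makes the
    estimator insensitive to gross outliers.
    """
    sigma = _validate_sigma(sigma)
    e = np.asarray(e, dtype=float)
    out = e * gaussian_kernel(e, sigma)
    return out if out.ndim else float(out)


def build_augmented_system(
    x_bar: np.ndarray,
    chi_bar: np.ndarray,
    g_y: np.ndarray,
    V: np.ndarray,
    factor: str = "symmetric",
) -> AugmentedSystem:
    """Whiten the stacked prior/pseudo-observation regression.

    ``factor`` selects the whitening factor: ``"symmetric"`` (default) uses the
    symmetric PSD square root, for which S @ S.T = S.T @ S = information block;
    ``"cholesky"`` uses the upper-triangular transpose of the Cholesky factor
    (S.T @ S = information).  Either choice leaves the Gaussian (sigma -> inf)
    limit identical; per-row kernel weights at finite sigma depend on the
    convention, which is fixed for reproducibility.
    """
    x_bar = np.atleast_1d(np.asarray(x_bar, dtype=float))
    g_y = np.atleast_1d(np.asarray(g_y, dtype=float))
    chi_bar = np.atleast_2d(np.asarray(chi_bar, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if factor == "symmetric":
        S_chi = spd_sqrt(chi_bar, name="prior information matrix chi_bar")
        S_V = spd_sqrt(V, name="residue information matrix V")
    elif factor == "cholesky":
        try:
            S_chi = np.linalg.cholesky(chi_bar).T
        except np.linalg.LinAlgError as exc:
            raise NotPositiveDefiniteError(
                "prior information matrix chi_bar is not positive definite"
            ) from exc
        try:
            S_V = np.linalg.cholesky(V).T
        except np.linalg.LinAlgError as exc:
            raise NotPositiveDefiniteError(
                "residue information matrix V is not positive definite"
            ) from exc
    else:
        raise ValueError(f"unknown whitening factor {factor!r}")
    D = np.concatenate([S_chi @ x_bar, S_V @ g_y])
    M = np.vstack([S_chi, S_V])
    if not np.all(np.isfinite(M)):
        raise ValueError("whitened observation model contains non-finite rows")
    return AugmentedSystem(D=D, M=M, S_chi=S_chi, S_V=S_V)


def correntropy_cost(x: np.ndarray, system: AugmentedSystem, sigma: float) -> float:
    """Correntropy cost (1/2n) sum_i G_sigma(d_i - m_i x); always in (0, 1]."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    residuals = system.D - system.M @ x
    return float(np.mean(gaussian_kernel(residuals, sigma)))


def _irls(
    system: AugmentedSystem,
    x0: np.ndarray,
    kernel: KernelSpec,
    settings: FixedPointSettings,
) -> FixedPointResult:
    """IRLS fixed point from one starting iterate (lagged-weight convention).

    Stops on the relative-change rule, on weight stationarity, or at the
    iteration cap; raises :class:`FilterDivergenceError` when the weighted
    normal equations collapse or the iterate blows up, advising a larger
    kernel bandwidth.
    """
    sigma = kernel.sigma
    D, M = system.D, system.M
    n = system.n
    scale = max(1.0, float(np.max(np.abs(D))))
    x_prev = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    c_prev = np.asarray(gaussian_kernel(D - M @ x_prev, sigma))
    x_new = x_prev
    converged = False
    iterations = settings.max_iter
    for t in range(1, settings.max_iter + 1):
        A = M.T @ (c_prev[:, None] * M)
        b = M.T @ (c_prev * D)
        try:
            x_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise FilterDivergenceError(
                "weighted normal equations are singular (all kernel weights "
                f"underflowed at sigma={sigma:g}); use a larger kernel bandwidth."
            ) from exc
        if not np.all(np.isfinite(x_new)) or np.linalg.norm(x_new) > 1e6 * scale:
            raise FilterDivergenceError(
                f"fixed-point iterate diverged at t={t} (sigma={sigma:g}); "
                "use a larger kernel bandwidth."
            )
        rel = np.linalg.norm(x_new - x_prev) / (np.linalg.norm(x_prev) + 1e-12)
        c_new = np.asarray(gaussian_kernel(D - M @ x_new, sigma))
        if rel <= settings.omega or np.max(np.abs(c_new - c_prev)) <= settings.weight_tol:
            converged = True
            iterations = t
            break
        if t == settings.max_iter:
            break  # keep c_prev = weights used in the final solve
        x_prev, c_prev = x_new, c_new
    # c_prev holds the weights used in the solve that produced x_new
    return FixedPointResult(
        x_hat=x_new,
        iterations=iterations,
        weights_chi=c_prev[:n].copy(),
        weights_V=c_prev[n:].copy(),
        converged=converged,
    )


def solve_augmented(
    system: AugmentedSystem,
    x0: np.ndarray,
    kernel: KernelSpec,
    settings: FixedPointSettings = FixedPointSettings(),
) -> FixedPointResult:
    """Solve the correntropy fixed point with a two-start IRLS.

    The cost is in general multimodal: when the innovation spans several
    whitened bandwidths there is one fixed point near the prior iterate and
    one near the least-squares solution.  The solver therefore runs IRLS from
    ``x0`` (the prior mean) and, at finite bandwidth, also from the
    least-squares solution, and keeps the least-squares basin only when its
    cost is higher by at least half a whitened row's worth (0.5 / 2n).  That
    margin separates the two multimodal regimes: with a near-vacuous prior
    (deviated initialization) the observation mode explains all 2n rows and
    wins decisively, whereas a gross outlier mode merely ties the prior mode
    (n rows each) and is rejected.  A single start suffices at the
    infinite-bandwidth sentinel, where the update is exactly least squares.
    """
    sigma = kernel.sigma
    if sigma < settings.min_sigma_guard:
        warnings.warn(
            f"kernel bandwidth {sigma:g} is below the divergence guard "
            f"{settings.min_sigma_guard:g}; the fixed point may diverge.",
            stacklevel=2,
        )
    res_prior = _irls(system, x0, kernel, settings)
    if np.isinf(sigma):
        return res_prior
    D, M = system.D, system.M
    x_ls, *_ = np.linalg.lstsq(M, D, rcond=None)
    if np.linalg.norm(x_ls - res_prior.x_hat) <= settings.omega * (
        np.linalg.norm(x_ls) + 1.0
    ):
        return res_prior  # both starts share the basin
    try:
        res_ls = _irls(system, x_ls, kernel, settings)
    except FilterDivergenceError:
        return res_prior
    cost_prior = correntropy_cost(res_prior.x_hat, system, sigma)
    cost_ls = correntropy_cost(res_ls.x_hat, system, sigma)
    if cost_ls > cost_prior + 0.5 / M.shape[0]:
        return res_ls
    return res_prior


def fixed_point_solve(
    x_bar: np.ndarray,
    chi_bar: np.ndarray,
    g_y: np.ndarray,
    V: np.ndarray,
    kernel: KernelSpec = KernelSpec(),
    settings: FixedPointSettings = FixedPointSettings(),
    factor: str = "symmetric",
) -> FixedPointResult:
    """Whiten, then solve the correntropy fixed point starting from x_bar."""
    system = build_augmented_system(x_bar, chi_bar, g_y, V, factor=factor)
    return solve_augmented(system, x_bar, kernel, settings)


def gain_form_update(
    x_bar: np.ndarray,
    chi_tilde: np.ndarray,
    V_tilde: np.ndarray,
    g_y: np.ndarray,
) -> np.ndarray:
    """Gain form of one IRLS pass: x_bar + (chi_tilde + V_tilde)^-1 V_tilde (g(y) - x_bar).

    Algebraically identical to the weighted-normal-equation form on the same
    weights; exposed for tests and for the information-filter reading of the
    update.
    """
    x_bar = np.atleast_1d(np.asarray(x_bar, dtype=float))
    g_y = np.atleast_1d(np.asarray(g_y, dtype=float))
    chi_tilde = np.atleast_2d(np.asarray(chi_tilde, dtype=float))
    V_tilde = np.atleast_2d(np.asarray(V_tilde, dtype=float))
    total = chi_tilde + V_tilde
    try:
        gain_step = np.linalg.solve(total, V_tilde @ (g_y - x_bar))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "chi_tilde + V_tilde is singular; cannot form the gain"
        ) from exc
    return x_bar + gain_step
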