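"""Per-step filter recursions: KF baseline, NIF, and the robust NMCIF.

All information-type filters share the prediction step

    x_bar_k   = F x_hat_{k-1} + q_mean
    chi_bar_k = W - W F (chi_hat_{k-1} + F' W F)^{-1} F' W

(the information-form of covariance prediction; it never inverts chi_hat, so a
near-zero initial information matrix — total initial uncertainty — is valid).
The nonlinear information filter (NIF) then fuses the pseudo-observation
g(y_k) = x_k + r_k with gain K = (chi_bar + V)^{-1} V; the nonlinear maximum
correntropy information filter (NMCIF) replaces that least-squares fusion with
the correntropy fixed point, and updates the posterior information matrix
either from the final IRLS weights (variant B, the default) or with the
asymptotic influence-function constant c(sigma, theta) (variant A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._linalg import symmetrize
from .correntropy import (
    FilterDivergenceError,
    FixedPointResult,
    FixedPointSettings,
    KernelSpec,
    build_augmented_system,
    solve_augmented,
)
from .state_space import LinearTuningModel, StateSpaceModel, TrialTrajectory

__all__ = [
    "FilterState",
    "PriorState",
    "InfoMatrixVariantConfig",
    "DecoderSpec",
    "DecodingResult",
    "predict",
    "nif_update",
    "nmcif_update",
    "asymptotic_info_constant",
    "kf_baseline_step",
    "run_filter",
]

DECODER_KINDS = ("kf", "nn", "nif", "nmcif_a", "nmcif_b")


@dataclass
class FilterState:
    """Posterior mean and information matrix at time index k."""

    x_hat: np.ndarray
    chi_hat: np.ndarray
    k: int = 0

    def __post_init__(self) -> None:
        self.x_hat = np.atleast_1d(np.asarray(self.x_hat, dtype=float))
        self.chi_hat = symmetrize(self.chi_hat)


@dataclass
class PriorState:
    """Predicted (prior) mean and information matrix."""

    x_bar: np.ndarray
    chi_bar: np.ndarray

    def __post_init__(self) -> None:
        self.x_bar = np.atleast_1d(np.asarray(self.x_bar, dtype=float))
        self.chi_bar = symmetrize(self.chi_bar)


@dataclass(frozen=True)
class InfoMatrixVariantConfig:
    """Choice of posterior information matrix.

    ``irls_B`` re-weights the whitened rows by the final kernel weights
    (row-wise outlier suppression, preferred at low state dimension);
    ``asymptotic_A`` scales M'M by the influence-function constant
    c(sigma, theta), where theta is the standard deviation of the reference
    whitened-residual distribution N(0, theta^2).
    """

    variant: str = "irls_B"
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("irls_B", "asymptotic_A"):
            raise ValueError(f"unknown information-matrix variant {self.variant!r}")
        if self.variant == "asymptotic_A":
            if self.theta is None or not self.theta > 0.0:
                raise ValueError("variant asymptotic_A requires theta > 0")


def predict(prev: FilterState, model: StateSpaceModel) -> PriorState:
    """Information-form prediction through the linear transition."""
    F, W = model.F, model.W
    x_bar = F @ prev.x_hat + model.q_mean
    inner = symmetrize(prev.chi_hat + F.T @ W @ F)
    try:
        inner_inv_FtW = np.linalg.solve(inner, F.T @ W)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "chi_hat + F' W F is singular in the prediction step"
        ) from exc
    chi_bar = symmetrize(W - W @ F @ inner_inv_FtW)
    return PriorState(x_bar=x_bar, chi_bar=chi_bar)


def nif_update(
    prior: PriorState,
    g_y: np.ndarray,
    V: np.ndarray,
    r_mean: np.ndarray | None = None,
) -> FilterState:
    """Nonlinear information filter update (the sigma -> inf special case)."""
    g_y = np.atleast_1d(np.asarray(g_y, dtype=float))
    if r_mean is not None:
        g_y = g_y - np.asarray(r_mean, dtype=float)
    V = np.atleast_2d(np.asarray(V, dtype=float))
    total = symmetrize(prior.chi_bar + V)
    try:
        step = np.linalg.solve(total, V @ (g_y - prior.x_bar))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("chi_bar + V is singular in the NIF update") from exc
    return FilterState(x_hat=prior.x_bar + step, chi_hat=total)


def asymptotic_info_constant(sigma: float, theta: float) -> float:
    """Influence-function information constant c(sigma, theta).

    c = (E[phi'(e)])^2 / E[phi(e)^2] for e ~ N(0, theta^2), which evaluates in
    closed form to sigma^3 (sigma^2 + 2 theta^2)^{3/2} /
    (theta^2 (sigma^2 + theta^2)^3).  As sigma -> inf, c -> 1/theta^2 and the
    posterior information reduces to M'M / theta^2.
    """
    if not theta > 0.0:
        raise ValueError("theta must be positive")
    if np.isinf(sigma):
        return 1.0 / theta**2
    s2, t2 = sigma**2, theta**2
    return sigma**3 * (s2 + 2.0 * t2) ** 1.5 / (t2 * (s2 + t2) ** 3)


def nmcif_update(
    prior: PriorState,
    g_y: np.ndarray,
    V: np.ndarray,
    kernel: KernelSpec,
    settings: FixedPointSettings = FixedPointSettings(),
    info_cfg: InfoMatrixVariantConfig = InfoMatrixVariantConfig(),
    r_mean: np.ndarray | None = None,
    factor: str = "symmetric",
) -> tuple[FilterState, FixedPointResult]:
    """Correntropy update: IRLS fixed point plus posterior information matrix.

    Returns the posterior filter state together with the fixed-point result
    (iteration count, final weights, convergence flag).
    """
    g_y = np.atleast_1d(np.asarray(g_y, dtype=float))
    if r_mean is not None:
        g_y = g_y - np.asarray(r_mean, dtype=float)
    system = build_augmented_system(prior.x_bar, prior.chi_bar, g_y, V, factor=factor)
    result = solve_augmented(system, prior.x_bar, kernel, settings)
    M = system.M
    if info_cfg.variant == "irls_B":
        c = result.weights
        chi_hat = M.T @ (c[:, None] * M)
    else:
        chi_hat = asymptotic_info_constant(kernel.sigma, info_cfg.theta) * (M.T @ M)
    return FilterState(x_hat=result.x_hat, chi_hat=symmetrize(chi_hat)), result


def kf_baseline_step(
    prev_mean: np.ndarray,
    prev_cov: np.ndarray,
    y_raw: np.ndarray,
    model: StateSpaceModel,
    tuning: LinearTuningModel,
) -> tuple[np.ndarray, np.ndarray]:
    """One covariance-form Kalman step on the raw m-channel measurement."""
    prev_mean = np.atleast_1d(np.asarray(prev_mean, dtype=float))
    prev_cov = symmetrize(prev_cov)
    y_raw = np.atleast_1d(np.asarray(y_raw, dtype=float))
    F, Q = model.F, model.Q
    H, R = tuning.H, tuning.R_obs
    x_bar = F @ prev_mean + model.q_mean
    P_bar = symmetrize(F @ prev_cov @ F.T + Q)
    innovation = y_raw - H @ x_bar - tuning.r_obs_mean
    S = symmetrize(H @ P_bar @ H.T + R)
    try:
        K = np.linalg.solve(S, H @ P_bar).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("innovation covariance is singular") from exc
    mean = x_bar + K @ innovation
    IKH = np.eye(model.n) - K @ H
    # Joseph form keeps the covariance PSD under roundoff
    cov = symmetrize(IKH @ P_bar @ IKH.T + K @ R @ K.T)
    return mean, cov


@dataclass(frozen=True)
class DecoderSpec:
    """Which decoder to run and with what robustness settings."""

    kind: str
    kernel: KernelSpec = KernelSpec()
    settings: FixedPointSettings = FixedPointSettings()
    theta: float | None = None
    factor: str = "symmetric"

    def __post_init__(self) -> None:
        if self.kind not in DECODER_KINDS:
            raise ValueError(f"unknown decoder {self.kind!r}; expected one of {DECODER_KINDS}")

    @property
    def label(self) -> str:
        if self.kind.startswith("nmcif"):
            return f"{self.kind}(sigma={self.kernel.sigma:g})"
        return self.kind

    def info_config(self) -> InfoMatrixVariantConfig:
        if self.kind == "nmcif_a":
            return InfoMatrixVariantConfig(variant="asymptotic_A", theta=self.theta or 1.0)
        return InfoMatrixVariantConfig(variant="irls_B")


@dataclass
class DecodingResult:
    """Per-step estimates with iteration counts and run metadata."""

    estimates: np.ndarray
    truth: np.ndarray | None
    iterations: np.ndarray
    converged: np.ndarray
    decoder: str
    settings: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    truncated_at: int | None = None

    def __len__(self) -> int:
        return self.estimates.shape[0]


def _empty_result(decoder: str, n: int, settings: dict[str, Any]) -> DecodingResult:
    return DecodingResult(
        estimates=np.zeros((0, n)),
        truth=np.zeros((0, n)),
        iterations=np.zeros(0, dtype=int),
        converged=np.zeros(0, dtype=bool),
        decoder=decoder,
        settings=settings,
    )


def run_filter(
    traj: TrialTrajectory,
    model: StateSpaceModel,
    decoder: DecoderSpec,
    *,
    pseudo_obs: np.ndarray | None = None,
    V: np.ndarray | None = None,
    r_mean: np.ndarray | None = None,
    tuning: LinearTuningModel | None = None,
    init_mean: np.ndarray | None = None,
    init_info: np.ndarray | float = 1e-6,
    init_cov: np.ndarray | float = 1.0,
    seed: int | None = None,
) -> DecodingResult:
    """Run one decoder over a full trajectory.

    Information filters (``nif``, ``nmcif_a``, ``nmcif_b``) and the ``nn``
    decoder consume the state-dimensional pseudo-observations ``pseudo_obs``
    (with residue information ``V``); the ``kf`` baseline consumes the raw
    firing in ``traj.firing`` through the fitted linear ``tuning``.

    Initialization defaults follow the task protocol: the first labeled state
    (else zeros) for the mean, information 1e-6 * I for the information
    filters, covariance 1 * I for the KF.  A divergence at any step truncates
    the result (``truncated_at``) rather than emitting NaNs.
    """
    n = model.n
    T = len(traj)
    settings_echo: dict[str, Any] = {
        "decoder": decoder.kind,
        "sigma": decoder.kernel.sigma,
        "omega": decoder.settings.omega,
        "max_iter": decoder.settings.max_iter,
    }
    truth = traj.states if traj.states.size else None
    if T == 0:
        return _empty_result(decoder.label, n, settings_echo)

    if init_mean is None:
        init_mean = traj.states[0] if truth is not None else np.zeros(n)
    init_mean = np.atleast_1d(np.asarray(init_mean, dtype=float))

    estimates = np.zeros((T, n))
    iterations = np.zeros(T, dtype=int)
    converged = np.ones(T, dtype=bool)
    truncated_at: int | None = None

    if decoder.kind == "nn":
        if pseudo_obs is None:
            raise ValueError("nn decoder requires pseudo_obs")
        estimates[:] = np.asarray(pseudo_obs, dtype=float)
        iterations[:] = 0
    elif decoder.kind == "kf":
        if tuning is None or traj.firing is None:
            raise ValueError("kf decoder requires traj.firing and a fitted tuning model")
        cov = np.eye(n) * init_cov if np.isscalar(init_cov) else symmetrize(init_cov)
        mean = init_mean
        for k in range(T):
            mean, cov = kf_baseline_step(mean, cov, traj.firing[k], model, tuning)
            estimates[k] = mean
    else:
        if pseudo_obs is None or V is None:
            raise ValueError(f"{decoder.kind} decoder requires pseudo_obs and V")
        pseudo_obs = np.atleast_2d(np.asarray(pseudo_obs, dtype=float))
        chi0 = np.eye(n) * init_info if np.isscalar(init_info) else symmetrize(init_info)
        state = FilterState(x_hat=init_mean, chi_hat=chi0, k=-1)
        info_cfg = decoder.info_config()
        for k in range(T):
            prior = predict(state, model)
            try:
                if decoder.kind == "nif":
                    state = nif_update(prior, pseudo_obs[k], V, r_mean=r_mean)
                    iterations[k] = 1
                else:
                    state, fp = nmcif_update(
                        prior,
                        pseudo_obs[k],
                        V,
                        decoder.kernel,
                        decoder.settings,
                        info_cfg,
                        r_mean=r_mean,
                        factor=decoder.factor,
                    )
                    iterations[k] = fp.iterations
                    converged[k] = fp.converged
            except FilterDivergenceError:
                truncated_at = k
                break
            state.k = k
            estimates[k] = state.x_hat
        if truncated_at is not None:
            estimates = estimates[:truncated_at]
            iterations = iterations[:truncated_at]
            converged = converged[:truncated_at]
            truth = truth[:truncated_at] if truth is not None else None

    return DecodingResult(
        estimates=estimates,
        truth=truth,
        iterations=iterations,
        converged=converged,
        decoder=decoder.label,
        settings=settings_echo,
        seed=seed,
        truncated_at=truncated_at,
    )
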