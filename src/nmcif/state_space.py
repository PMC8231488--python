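"""State-observation model of the decoding task and its least-squares fits.

The behavioral state x_k (2-D lever position code in the two-lever task)
evolves linearly,

    x_k = F x_{k-1} + q_{k-1},        q ~ (q_mean, Q),  W = Q^{-1},

while the measurements are either the raw multi-channel binned firing rates
(linear tuning y_k = H x_k + zeta_k, used by the Kalman-filter baseline) or a
learned state-dimensional pseudo-observation g(y_k) = x_k + r_k with residue
information V = R^{-1} (used by the information filters).

All parameters are estimated from labeled training trajectories by ordinary
least squares; noise statistics come from the fit residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._linalg import (
    NotPositiveDefiniteError,
    floor_covariance,
    regularize_spd,
    spd_inverse,
    symmetrize,
)

__all__ = [
    "StateSpaceModel",
    "LinearTuningModel",
    "PseudoObservationModel",
    "TrialTrajectory",
    "fit_transition",
    "fit_linear_tuning",
    "estimate_residue_information",
]

#: Fitted noise mean larger than this fraction of the state scale raises a
#: warning flag (the filter model assumes zero-mean noise).
MEAN_FLAG_FRACTION = 0.1


@dataclass
class StateSpaceModel:
    """Linear state-transition model with process-noise information matrix."""

    F: np.ndarray
    q_mean: np.ndarray
    Q: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        self.q_mean = np.atleast_1d(np.asarray(self.q_mean, dtype=float))
        self.Q = symmetrize(self.Q)
        self.W = symmetrize(self.W)
        if self.n < 1 or not np.all(np.isfinite(self.F)):
            raise ValueError("transition matrix must be finite with n >= 1")

    @property
    def n(self) -> int:
        return self.F.shape[0]


@dataclass
class LinearTuningModel:
    """Per-channel linear tuning y = H x + r_obs, for the KF baseline only."""

    H: np.ndarray
    r_obs_mean: np.ndarray
    R_obs: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.r_obs_mean = np.atleast_1d(np.asarray(self.r_obs_mean, dtype=float))
        self.R_obs = symmetrize(self.R_obs)


@dataclass
class PseudoObservationModel:
    """Pseudo-observation layer g(y) = x + r with residue information V."""

    g: Callable[[np.ndarray], np.ndarray] | None
    r_mean: np.ndarray
    R: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.r_mean = np.atleast_1d(np.asarray(self.r_mean, dtype=float))
        self.R = symmetrize(self.R)
        self.V = symmetrize(self.V)


@dataclass
class TrialTrajectory:
    """Time-aligned behavioral states and binned firing with trial events.

    ``times`` are bin indices (100-ms bins by default), ``states`` is T x n,
    ``firing`` is T x m (may be None for state-only trajectories), and
    ``events`` is a list of (bin_index, label) markers such as start cue,
    press, and feedback.
    """

    times: np.ndarray
    states: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)
    firing: np.ndarray | None = None
    bin_ms: float = 100.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.firing is not None:
            self.firing = np.atleast_2d(np.asarray(self.firing, dtype=float))
            if self.firing.shape[0] != self.states.shape[0]:
                raise ValueError("states and firing must share the time axis")
            if np.any(self.firing < 0):
                raise ValueError("firing entries must be nonnegative")

    def __len__(self) -> int:
        return self.states.shape[0]


def _check_design(X: np.ndarray, labels: Sequence[str]) -> None:
    """Raise on a singular regressor Gram matrix, naming the deficient dimension."""
    gram = X.T @ X
    eigvals, eigvecs = np.linalg.eigh(symmetrize(gram))
    scale = max(eigvals[-1], 0.0)
    if eigvals[0] <= 1e-10 * max(scale, 1e-30) or scale == 0.0:
        deficient = int(np.argmax(np.abs(eigvecs[:, 0])))
        raise np.linalg.LinAlgError(
            "singular regressor Gram matrix: design is rank-deficient along "
            f"dimension '{labels[deficient]}'; the training states do not span "
            "the state space."
        )


def fit_transition(
    states: np.ndarray, assume_zero_mean: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit of the linear state transition and its noise statistics.

    Regresses x_k on x_{k-1} over the whole trajectory.  With
    ``assume_zero_mean`` (the default, matching the filter model's zero-mean
    noise assumption) no intercept is fitted and q_mean is zero; otherwise an
    intercept is fitted internally and folded into q_mean.

    Returns
    -------
    (F, q_mean, Q, W)
        Transition matrix, process-noise mean, covariance and information
        matrix W = Q^{-1} (jitter-regularized when near-singular).
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    T, n = states.shape
    if T < n + 1:
        raise ValueError(f"need at least n+1={n + 1} time bins, got {T}")
    if not np.all(np.isfinite(states)):
        raise ValueError("states must be finite")

    X = states[:-1]
    Y = states[1:]
    labels = [f"x{i + 1}" for i in range(n)]
    if not assume_zero_mean:
        X = np.hstack([X, np.ones((T - 1, 1))])
        labels.append("intercept")
    _check_design(X, labels)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    if assume_zero_mean:
        F = coef.T
        q_mean = np.zeros(n)
        residues = Y - X @ coef
        # second moment about zero, consistent with the zero-mean assumption
        Q = symmetrize(residues.T @ residues / max(T - 2, 1))
    else:
        F = coef[:n].T
        intercept = coef[n]
        residues = Y - X @ coef
        q_mean = intercept + residues.mean(axis=0)
        residues = states[1:] - states[:-1] @ F.T - q_mean
        Q = symmetrize(np.atleast_2d(np.cov(residues.T, ddof=1)))
    W = spd_inverse(Q, name="process-noise covariance Q", abs_floor=1e-12)
    return F, q_mean, Q, W


def fit_linear_tuning(
    states: np.ndarray,
    firing: np.ndarray,
    var_floor: float = 1e-8,
    diagonal: bool = False,
) -> LinearTuningModel:
    """Fit each channel's linear tuning to the state independently.

    Each row h_i of H is the least-squares regression of channel i on the
    state; the intercept is folded into the residual mean ``r_obs_mean``.
    Channels with (near) zero residual variance are floored at ``var_floor``
    with a warning.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    firing = np.atleast_2d(np.asarray(firing, dtype=float))
    T, n = states.shape
    if firing.shape[0] != T:
        raise ValueError("states and firing must share the time axis")
    if T < n + 1:
        raise ValueError(f"need at least n+1={n + 1} time bins, got {T}")

    X = np.hstack([states, np.ones((T, 1))])
    labels = [f"x{i + 1}" for i in range(n)] + ["intercept"]
    _check_design(X, labels)
    coef, *_ = np.linalg.lstsq(X, firing, rcond=None)
    H = coef[:n].T
    r_obs_mean = coef[n]
    residues = firing - states @ H.T - r_obs_mean
    if diagonal:
        R_obs = np.diag(residues.var(axis=0, ddof=1))
    else:
        R_obs = np.atleast_2d(np.cov(residues.T, ddof=1))
    R_obs = floor_covariance(R_obs, var_floor, name="observation residual covariance")
    return LinearTuningModel(H=H, r_obs_mean=r_obs_mean, R_obs=R_obs)


def estimate_residue_information(
    residues: np.ndarray,
    state_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample mean/covariance of model residues and the information matrix V.

    The filters assume zero-mean residues; a warning is emitted when the
    fitted mean exceeds ``MEAN_FLAG_FRACTION`` of ``state_scale``.

    Returns
    -------
    (r_mean, R, V)
        with V = R^{-1} after symmetric jitter regularization, so that
        V @ R = I to numerical tolerance.

    Raises
    ------
    NotPositiveDefiniteError
        For rank-deficient residue covariance (e.g. all-zero residues), with
        jitter guidance in the message.
    """
    residues = np.atleast_2d(np.asarray(residues, dtype=float))
    T, n = residues.shape
    if T < n + 1:
        raise ValueError(f"need at least n+1={n + 1} residue rows, got {T}")
    r_mean = residues.mean(axis=0)
    if np.linalg.norm(r_mean) > MEAN_FLAG_FRACTION * state_scale:
        warnings.warn(
            f"residue mean {r_mean} exceeds {MEAN_FLAG_FRACTION:.0%} of the "
            "state scale; the zero-mean noise assumption looks violated.",
            stacklevel=2,
        )
    R = np.atleast_2d(np.cov(residues.T, ddof=1))
    R = regularize_spd(R, name="residue covariance R")
    V = spd_inverse(R, name="residue covariance R")
    return r_mean, R, V


def pseudo_observation_model_from_residues(
    residues: np.ndarray,
    g: Callable[[np.ndarray], np.ndarray] | None = None,
    var_floor: float = 0.0,
) -> PseudoObservationModel:
    """Convenience: build a PseudoObservationModel from observer residues."""
    r_mean, R, _ = estimate_residue_information(residues)
    if var_floor > 0.0:
        R = floor_covariance(R, var_floor, name="pseudo-observation residue covariance")
    V = spd_inverse(R, name="pseudo-observation residue covariance")
    return PseudoObservationModel(g=g, r_mean=r_mean, R=R, V=V)
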