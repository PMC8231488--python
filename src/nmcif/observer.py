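"""Neural-network preprocessor g(.): firing-rate history -> pseudo-observation.

A one-hidden-layer perceptron (tanh hidden units, linear output) regresses the
2-D behavioral state on the current bin of multi-channel firing rates plus a
short history window (default 4 past bins + current at 100 ms = 400 ms of
history, i.e. 32 channels -> 160 inputs).  Training is full-batch steepest
gradient descent on the mean squared error; weights are initialized multiple
times and the restart with the lowest held-out MSE is kept.  The training-split
residuals g(y) - x supply the residue statistics (r_mean, R, V) that the
information filters consume.

scikit-learn's MLPRegressor performs the gradient-descent training; the fitted
weights are then extracted into a plain numpy forward pass so that prediction
and serialization are deterministic and self-contained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from ._linalg import floor_covariance, spd_inverse, symmetrize
from .state_space import estimate_residue_information

__all__ = [
    "ObserverConfig",
    "TrainedObserver",
    "make_lagged_features",
    "train_observer",
    "apply_observer",
]


@dataclass(frozen=True)
class ObserverConfig:
    """Architecture, history window, and training settings of the observer."""

    n_hidden: int = 10
    history_bins: int = 4
    n_restarts: int = 20
    train_fraction: float = 0.6
    learning_rate: float = 0.05
    epochs: int = 2000
    seed: int = 0
    random_split: bool = False  # contiguous split by default (time-series hygiene)
    var_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.history_bins < 0:
            raise ValueError("history_bins must be >= 0")


@dataclass
class TrainedObserver:
    """Weights of the fitted perceptron plus residue statistics.

    The forward pass is out = tanh(z W1 + b1) W2 + b2 on standardized
    features z = (f - x_mean) / x_scale.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    r_mean: np.ndarray
    R: np.ndarray
    V: np.ndarray
    loss_curve: list[float] = field(default_factory=list)
    val_mse: float = float("nan")
    restart_index: int = -1
    history_bins: int = 0

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W2.shape[1]


def make_lagged_features(firing: np.ndarray, history_bins: int) -> np.ndarray:
    """Stack the current bin with ``history_bins`` past bins per row.

    Row k concatenates bins k, k-1, ..., k-history_bins (current first).
    Leading rows are padded by repeating the first bin, so the output stays
    aligned with the state at bin k and no trial-start rows are lost.
    """
    firing = np.atleast_2d(np.asarray(firing, dtype=float))
    T, m = firing.shape
    if T <= history_bins:
        raise ValueError(
            f"need more than history_bins={history_bins} time bins, got {T}"
        )
    if history_bins == 0:
        return firing.copy()
    blocks = []
    for lag in range(history_bins + 1):
        shifted = np.vstack([np.repeat(firing[:1], lag, axis=0), firing[: T - lag]])
        blocks.append(shifted)
    return np.hstack(blocks)


def _contiguous_split(T: int, train_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    cut = int(round(T * train_fraction))
    cut = min(max(cut, 1), T - 1)
    idx = np.arange(T)
    return idx[:cut], idx[cut:]


def train_observer(
    features: np.ndarray, states: np.ndarray, cfg: ObserverConfig
) -> TrainedObserver:
    """Train the observer with multiple restarts and keep the best on held-out MSE.

    The 60/40 split is contiguous by default to avoid temporal leakage
    (``cfg.random_split`` switches to random rows).  Restarts with non-finite
    loss are skipped with a warning; ties in held-out MSE resolve to the
    lowest restart index, so permuting the restart order cannot change the
    selected model.  Residue statistics are computed on the training split.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if features.shape[0] != states.shape[0]:
        raise ValueError("features and states must share the time axis")
    T = features.shape[0]
    if cfg.random_split:
        rng = np.random.default_rng(cfg.seed)
        perm = rng.permutation(T)
        cut = int(round(T * cfg.train_fraction))
        train_idx, val_idx = np.sort(perm[:cut]), np.sort(perm[cut:])
    else:
        train_idx, val_idx = _contiguous_split(T, cfg.train_fraction)

    x_mean = features[train_idx].mean(axis=0)
    x_scale = features[train_idx].std(axis=0)
    x_scale[x_scale < 1e-12] = 1.0
    z_train = (features[train_idx] - x_mean) / x_scale
    z_val = (features[val_idx] - x_mean) / x_scale
    y_train = states[train_idx]
    y_val = states[val_idx]

    best: tuple[float, int, MLPRegressor] | None = None
    for restart in range(cfg.n_restarts):
        net = MLPRegressor(
            hidden_layer_sizes=(cfg.n_hidden,),
            activation="tanh",
            solver="sgd",
            alpha=0.0,
            batch_size=len(train_idx),
            learning_rate="constant",
            learning_rate_init=cfg.learning_rate,
            momentum=0.0,
            nesterovs_momentum=False,
            shuffle=False,
            max_iter=cfg.epochs,
            tol=1e-7,
            n_iter_no_change=25,
            random_state=cfg.seed + restart,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            try:
                net.fit(z_train, y_train)
            except ValueError as exc:  # divergent learning rate -> non-finite loss
                warnings.warn(
                    f"restart {restart} skipped (non-finite training loss: {exc})",
                    stacklevel=2,
                )
                continue
        if not np.isfinite(net.loss_):
            warnings.warn(f"restart {restart} skipped (non-finite loss)", stacklevel=2)
            continue
        pred_val = net.predict(z_val).reshape(len(val_idx), -1)
        val_mse = float(np.mean(np.sum((pred_val - y_val) ** 2, axis=1)))
        if best is None or val_mse < best[0]:
            best = (val_mse, restart, net)
    if best is None:
        raise RuntimeError(
            "all observer restarts diverged; lower the learning rate"
        )
    val_mse, restart_index, net = best

    W1 = np.asarray(net.coefs_[0], dtype=float)
    b1 = np.asarray(net.intercepts_[0], dtype=float)
    W2 = np.asarray(net.coefs_[1], dtype=float)
    b2 = np.asarray(net.intercepts_[1], dtype=float)

    pred_train = np.tanh(z_train @ W1 + b1) @ W2 + b2
    residues = pred_train - y_train
    try:
        r_mean, R, V = estimate_residue_information(residues)
    except np.linalg.LinAlgError:
        # near-perfect observer: floor the residue covariance instead of failing
        r_mean = residues.mean(axis=0)
        R = symmetrize(np.atleast_2d(np.cov(residues.T, ddof=1)))
        R = floor_covariance(R, cfg.var_floor, name="observer residue covariance")
        V = spd_inverse(R, name="observer residue covariance")
    R = floor_covariance(R, cfg.var_floor, name="observer residue covariance")
    V = spd_inverse(R, name="observer residue covariance")

    return TrainedObserver(
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        x_mean=x_mean,
        x_scale=x_scale,
        r_mean=r_mean,
        R=R,
        V=V,
        loss_curve=[float(v) for v in net.loss_curve_],
        val_mse=val_mse,
        restart_index=restart_index,
        history_bins=cfg.history_bins,
    )


def apply_observer(obs: TrainedObserver, features: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; accepts a single row or a T x p matrix."""
    features = np.asarray(features, dtype=float)
    single = features.ndim == 1
    features = np.atleast_2d(features)
    if features.shape[1] != obs.n_inputs:
        raise ValueError(
            f"feature width {features.shape[1]} does not match the trained "
            f"observer input width {obs.n_inputs}"
        )
    z = (features - obs.x_mean) / obs.x_scale
    out = np.tanh(z @ obs.W1 + obs.b1) @ obs.W2 + obs.b2
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("observer produced non-finite outputs")
    return out[0] if single else out
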