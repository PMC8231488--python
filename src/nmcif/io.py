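"""Delimited-text and JSON persistence for trajectories, models, and results.

Formats are deliberately plain: states as CSV with columns ``t,x1,x2``,
firing as CSV with ``t,ch1..chm``, fitted models and observers as JSON with
matrices stored as row-major nested lists, decoding results as CSV with a
JSON summary next to them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .filters import DecodingResult
from .observer import TrainedObserver
from .state_space import LinearTuningModel, StateSpaceModel, TrialTrajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_state_space_model",
    "read_state_space_model",
    "write_tuning_model",
    "read_tuning_model",
    "write_observer",
    "read_observer",
    "write_decoding_result",
    "read_decoding_result",
]


def write_trajectory(traj: TrialTrajectory, states_path: str | Path, firing_path: str | Path | None = None) -> None:
    n = traj.states.shape[1]
    frame = pd.DataFrame(traj.states, columns=[f"x{i + 1}" for i in range(n)])
    frame.insert(0, "t", traj.times)
    frame.to_csv(states_path, index=False)
    if firing_path is not None and traj.firing is not None:
        m = traj.firing.shape[1]
        fframe = pd.DataFrame(traj.firing, columns=[f"ch{i + 1}" for i in range(m)])
        fframe.insert(0, "t", traj.times)
        fframe.to_csv(firing_path, index=False)


def read_trajectory(
    states_path: str | Path,
    firing_path: str | Path | None = None,
    bin_ms: float = 100.0,
) -> TrialTrajectory:
    sframe = pd.read_csv(states_path)
    times = sframe["t"].to_numpy()
    states = sframe.drop(columns="t").to_numpy(dtype=float)
    firing = None
    if firing_path is not None:
        fframe = pd.read_csv(firing_path)
        firing = fframe.drop(columns="t").to_numpy(dtype=float)
    return TrialTrajectory(times=times, states=states, firing=firing, bin_ms=bin_ms)


def _mat(a: np.ndarray) -> list:
    return np.asarray(a, dtype=float).tolist()


def write_state_space_model(model: StateSpaceModel, path: str | Path) -> None:
    payload = {
        "F": _mat(model.F),
        "q_mean": _mat(model.q_mean),
        "Q": _mat(model.Q),
        "W": _mat(model.W),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_state_space_model(path: str | Path) -> StateSpaceModel:
    payload = json.loads(Path(path).read_text())
    return StateSpaceModel(
        F=np.array(payload["F"]),
        q_mean=np.array(payload["q_mean"]),
        Q=np.array(payload["Q"]),
        W=np.array(payload["W"]),
    )


def write_tuning_model(tuning: LinearTuningModel, path: str | Path) -> None:
    payload = {
        "H": _mat(tuning.H),
        "r_obs_mean": _mat(tuning.r_obs_mean),
        "R_obs": _mat(tuning.R_obs),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_tuning_model(path: str | Path) -> LinearTuningModel:
    payload = json.loads(Path(path).read_text())
    return LinearTuningModel(
        H=np.array(payload["H"]),
        r_obs_mean=np.array(payload["r_obs_mean"]),
        R_obs=np.array(payload["R_obs"]),
    )


def write_observer(obs: TrainedObserver, path: str | Path) -> None:
    payload = {
        "architecture": {
            "n_inputs": obs.n_inputs,
            "n_hidden": obs.W1.shape[1],
            "n_outputs": obs.n_outputs,
            "activation": "tanh",
            "history_bins": obs.history_bins,
        },
        "W1": _mat(obs.W1),
        "b1": _mat(obs.b1),
        "W2": _mat(obs.W2),
        "b2": _mat(obs.b2),
        "x_mean": _mat(obs.x_mean),
        "x_scale": _mat(obs.x_scale),
        "r_mean": _mat(obs.r_mean),
        "R": _mat(obs.R),
        "V": _mat(obs.V),
        "val_mse": obs.val_mse,
        "restart_index": obs.restart_index,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_observer(path: str | Path) -> TrainedObserver:
    payload = json.loads(Path(path).read_text())
    return TrainedObserver(
        W1=np.array(payload["W1"]),
        b1=np.array(payload["b1"]),
        W2=np.array(payload["W2"]),
        b2=np.array(payload["b2"]),
        x_mean=np.array(payload["x_mean"]),
        x_scale=np.array(payload["x_scale"]),
        r_mean=np.array(payload["r_mean"]),
        R=np.array(payload["R"]),
        V=np.array(payload["V"]),
        val_mse=payload["val_mse"],
        restart_index=payload["restart_index"],
        history_bins=payload["architecture"]["history_bins"],
    )


def write_decoding_result(result: DecodingResult, path: str | Path) -> None:
    """Write per-step estimates as CSV: t, xhat*, truth*, iterations, converged."""
    T, n = result.estimates.shape
    frame = pd.DataFrame({"t": np.arange(T)})
    for i in range(n):
        frame[f"xhat{i + 1}"] = result.estimates[:, i]
    for i in range(n):
        truth_col = result.truth[:, i] if result.truth is not None else np.full(T, np.nan)
        frame[f"truth{i + 1}"] = truth_col
    frame["iterations"] = result.iterations
    frame["converged"] = result.converged.astype(int)
    frame.to_csv(path, index=False)


def read_decoding_result(path: str | Path) -> DecodingResult:
    frame = pd.read_csv(path)
    xhat_cols = [c for c in frame.columns if c.startswith("xhat")]
    truth_cols = [c for c in frame.columns if c.startswith("truth")]
    truth = frame[truth_cols].to_numpy(dtype=float)
    return DecodingResult(
        estimates=frame[xhat_cols].to_numpy(dtype=float),
        truth=None if np.all(np.isnan(truth)) else truth,
        iterations=frame["iterations"].to_numpy(dtype=int),
        converged=frame["converged"].to_numpy(dtype=bool),
        decoder=str(Path(path).stem),
    )
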