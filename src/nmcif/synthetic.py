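"""Synthetic two-lever-task data: states, firing, contamination, benchmarks.

Emulates the rodent two-lever discrimination paradigm in 100-ms bins: each
trial rests at [0, 0], ramps smoothly (logistic sigmoid) to the instructed
lever target — [1, 1] for the high lever, [1, -1] for the low lever — holds
there, and returns to rest over 200 ms.  Firing is generated from the state
through either a linear-Gaussian tuning or a linear-nonlinear-Poisson (LNP)
spike-count model with per-bin counts of order 0-5, as typical for cortical
units at 100 ms.  Optional shot-noise contamination reproduces heavy-tailed
measurement residues (a small fraction of bins receives additive noise with a
large variance multiplier), and a benchmark suite packages the three
experiment conditions (clean, deviated initialization, contaminated) with
10 paired test segments each.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .state_space import TrialTrajectory

__all__ = [
    "TaskScenario",
    "TuningSpec",
    "ContaminationSpec",
    "InitDeviationSpec",
    "generate_states",
    "generate_firing",
    "generate_pseudo_observations",
    "contaminate",
    "make_benchmark_suite",
]

REST_TARGET = np.array([0.0, 0.0])
HIGH_TARGET = np.array([1.0, 1.0])
LOW_TARGET = np.array([1.0, -1.0])

#: Maximum log-rate allowed in the LNP model before the rate is declared
#: overflowing (exp(30) counts per bin is far beyond physiology).
MAX_LOG_RATE = 30.0


@dataclass(frozen=True)
class TaskScenario:
    """Trial structure of the simulated two-lever task (durations in bins)."""

    n_trials: int = 10
    p_high: float = 0.4
    bin_ms: float = 100.0
    pre_cue_bins: int = 5
    press_approach_bins: int = 5
    hold_bins: int = 5
    return_bins: int = 2
    sigmoid_steepness: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pre_cue_bins", "press_approach_bins", "hold_bins", "return_bins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1 bin")
        if self.hold_bins < 5:
            raise ValueError("hold_bins must be >= 5 (>= 500 ms hold)")
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError("p_high must be a probability")


@dataclass(frozen=True)
class TuningSpec:
    """How the m channels tune to the 2-D state.

    ``linear_gaussian``: y = A x + b + noise_scale * N(0, I), an idealized rate
    code used for exactness tests and for the KF baseline's model.
    ``lnp_poisson`` (default): counts ~ Poisson(exp(a_c . x + b_c)), the
    biologically flavored spike-count model.
    """

    m: int = 32
    mode: str = "lnp_poisson"
    A: np.ndarray | None = None
    b: np.ndarray | None = None
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("linear_gaussian", "lnp_poisson"):
            raise ValueError(f"unknown tuning mode {self.mode!r}")

    def materialize(self, n: int = 2) -> "TuningSpec":
        """Draw default tuning parameters when A or b were not supplied.

        LNP gains are scaled so per-bin counts stay O(0-5); linear-Gaussian
        tuning is deliberately weak and noisy (single-bin SNR well below 1),
        as for cortical units in 100-ms bins.
        """
        if self.A is not None and self.b is not None:
            return self
        rng = np.random.default_rng(self.seed)
        if self.mode == "lnp_poisson":
            A = self.A if self.A is not None else rng.normal(0.0, 0.35, size=(self.m, n))
            b = self.b if self.b is not None else np.log(rng.uniform(0.5, 3.0, size=self.m))
        else:
            A = self.A if self.A is not None else rng.normal(0.0, 0.3, size=(self.m, n))
            b = self.b if self.b is not None else rng.uniform(0.5, 2.0, size=self.m)
        return replace(self, A=np.asarray(A, dtype=float), b=np.asarray(b, dtype=float))


@dataclass(frozen=True)
class ContaminationSpec:
    """Shot-noise contamination of a fraction of time bins."""

    fraction: float = 0.033
    magnitude: float = 100.0
    target: str = "pseudo_observation"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("fraction must be in [0, 1)")
        if self.target not in ("raw_measurement", "pseudo_observation"):
            raise ValueError(f"unknown contamination target {self.target!r}")


@dataclass(frozen=True)
class InitDeviationSpec:
    """Offset added to the true initial state when initializing a decoder."""

    offset: tuple[float, ...] = (3.0, 3.0)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offset must be finite")


def _sigmoid_ramp(a: np.ndarray, b: np.ndarray, length: int, steepness: float) -> np.ndarray:
    """Monotone logistic ramp from a to b over ``length`` interior bins.

    Endpoints are virtual (the surrounding plateaus), so every ramp bin lies
    strictly between the plateau values.
    """
    i = np.arange(1, length + 1, dtype=float)
    center = (length + 1) / 2.0
    u = expit(steepness * (i - center))
    u0 = expit(steepness * (0.0 - center))
    u1 = expit(steepness * (length + 1 - center))
    u = (u - u0) / (u1 - u0)
    return a + u[:, None] * (b - a)


def generate_states(scen: TaskScenario) -> TrialTrajectory:
    """Concatenated per-trial state trajectories with event annotations.

    Per trial: rest plateau -> sigmoid rise to the drawn lever target ->
    hold plateau -> sigmoid return to rest.  Deterministic given the seed.
    """
    rng = np.random.default_rng(scen.seed)
    # fixed session composition: round(p_high * n_trials) high-lever trials in
    # shuffled order, emulating the realized trial counts of a session
    n_high = int(round(scen.p_high * scen.n_trials))
    is_high = np.concatenate(
        [np.ones(n_high, dtype=bool), np.zeros(scen.n_trials - n_high, dtype=bool)]
    )
    rng.shuffle(is_high)
    segments: list[np.ndarray] = []
    events: list[tuple[int, str]] = []
    cursor = 0
    for trial in range(scen.n_trials):
        target = HIGH_TARGET if is_high[trial] else LOW_TARGET
        rest = np.tile(REST_TARGET, (scen.pre_cue_bins, 1))
        approach = _sigmoid_ramp(
            REST_TARGET, target, scen.press_approach_bins, scen.sigmoid_steepness
        )
        hold = np.tile(target, (scen.hold_bins, 1))
        back = _sigmoid_ramp(target, REST_TARGET, scen.return_bins, scen.sigmoid_steepness)
        events.append((cursor + scen.pre_cue_bins, "start_cue"))
        events.append((cursor + scen.pre_cue_bins + scen.press_approach_bins, "press"))
        events.append(
            (
                cursor + scen.pre_cue_bins + scen.press_approach_bins + scen.hold_bins,
                "feedback",
            )
        )
        trial = np.vstack([rest, approach, hold, back])
        segments.append(trial)
        cursor += trial.shape[0]
    states = np.vstack(segments)
    times = np.arange(states.shape[0])
    return TrialTrajectory(times=times, states=states, events=events, bin_ms=scen.bin_ms)


def generate_firing(
    states: np.ndarray, tuning: TuningSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Generate T x m firing from the state under the given tuning model."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    tuning = tuning.materialize(n=states.shape[1])
    if rng is None:
        rng = np.random.default_rng(tuning.seed)
    drive = states @ tuning.A.T + tuning.b
    if tuning.mode == "linear_gaussian":
        return drive + tuning.noise_scale * rng.standard_normal(drive.shape)
    if np.max(drive) > MAX_LOG_RATE:
        raise ValueError(
            f"LNP log-rate exceeds {MAX_LOG_RATE} (rate overflow); use smaller "
            "tuning gains."
        )
    return rng.poisson(np.exp(drive)).astype(float)


def generate_pseudo_observations(
    states: np.ndarray,
    residual_std: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Synthetic pseudo-observations g(y) = x + r with r ~ N(0, residual_std^2 I).

    Emulates the output of a trained observer directly at the accuracy level a
    perceptron reaches on this task, so filter-level experiments do not need to
    retrain a network per replicate.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return states + residual_std * rng.standard_normal(states.shape)


def contaminate(
    data: np.ndarray,
    spec: ContaminationSpec,
    baseline_var: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Add zero-mean shot noise to a seeded random subset of time bins.

    Exactly ``floor(fraction * T)`` bins receive additive Gaussian shots with
    per-column variance ``magnitude * baseline_var``; ``baseline_var`` defaults
    to the per-column sample variance of ``data`` (pass the model's residue
    variance when contaminating pseudo-observations).  Returns the contaminated
    copy and the sorted ground-truth outlier indices; clean bins are preserved
    bitwise.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    T = data.shape[0]
    k = int(np.floor(spec.fraction * T))
    out = data.copy()
    if k == 0:
        return out, np.zeros(0, dtype=int)
    rng = np.random.default_rng(spec.seed)
    idx = np.sort(rng.choice(T, size=k, replace=False))
    if baseline_var is None:
        baseline_var = data.var(axis=0)
    shot_std = np.sqrt(spec.magnitude * np.broadcast_to(baseline_var, (data.shape[1],)))
    out[idx] += rng.standard_normal((k, data.shape[1])) * shot_std
    return out, idx


def make_benchmark_suite(
    seed: int,
    scenario: TaskScenario | None = None,
    tuning: TuningSpec | None = None,
    n_test_segments: int = 10,
    trials_per_segment: int = 3,
    train_trials: int = 100,
    contamination: ContaminationSpec | None = None,
    init_deviation: InitDeviationSpec | None = None,
    pseudo_residual_std: float = 0.2,
) -> dict:
    """Build the three-condition benchmark bundle with train/test separation.

    Returns a dict with a shared ``train`` trajectory, ``segments`` (the 10
    clean test segments, states + firing), per-condition entries (``clean``,
    ``bad_init``, ``contaminated``) describing how the shared segments are to
    be decoded, and the generator specs used.  Clean and contaminated
    conditions share identical underlying states and firing; contamination
    applies to the measurement side (pseudo-observation residues by default)
    at decode time, mirroring a paired design.
    """
    scenario = scenario or TaskScenario()
    tuning = (tuning or TuningSpec()).materialize()
    contamination = contamination or ContaminationSpec()
    init_deviation = init_deviation or InitDeviationSpec()

    root = np.random.SeedSequence(seed)
    train_ss, tuning_ss, *segment_ss = root.spawn(2 + n_test_segments)

    def _make_traj(scen: TaskScenario, rng: np.random.Generator) -> TrialTrajectory:
        traj = generate_states(scen)
        traj.firing = generate_firing(traj.states, tuning, rng=rng)
        return traj

    train_scen = replace(
        scenario, n_trials=train_trials, seed=int(train_ss.generate_state(1)[0] % 2**31)
    )
    train = _make_traj(train_scen, np.random.default_rng(tuning_ss))

    segments: list[TrialTrajectory] = []
    for ss in segment_ss:
        seg_seed = int(ss.generate_state(1)[0] % 2**31)
        seg_scen = replace(scenario, n_trials=trials_per_segment, seed=seg_seed)
        segments.append(_make_traj(seg_scen, np.random.default_rng(ss.spawn(1)[0])))

    return {
        "seed": seed,
        "train": train,
        "segments": segments,
        "tuning": tuning,
        "pseudo_residual_std": pseudo_residual_std,
        "conditions": {
            "clean": {"contamination": None, "init_offset": None},
            "bad_init": {
                "contamination": None,
                "init_offset": np.asarray(init_deviation.offset, dtype=float),
            },
            "contaminated": {"contamination": contamination, "init_offset": None},
        },
    }
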