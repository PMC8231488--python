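"""Shared fixtures: random SPD matrices and fitted synthetic decoding problems."""

from types import SimpleNamespace

import numpy as np
import pytest

from nmcif.state_space import (
    StateSpaceModel,
    estimate_residue_information,
    fit_linear_tuning,
    fit_transition,
)
from nmcif.synthetic import (
    TaskScenario,
    TuningSpec,
    generate_firing,
    generate_pseudo_observations,
    generate_states,
)


def make_spd(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random symmetric positive definite matrix."""
    A = rng.normal(size=(n, n))
    return scale * (A @ A.T + 0.5 * n * np.eye(n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def build_decoding_problem(
    seed: int,
    test_trials: int = 12,
    train_trials: int = 20,
    residual_std: float = 0.2,
    with_firing: bool = False,
    tuning_mode: str = "linear_gaussian",
):
    """Fit the state-space model on a training run of the two-lever task and
    return it with a paired test run and its synthetic pseudo-observations.

    When ``with_firing`` is set, linear-Gaussian (or LNP) firing is generated
    for both runs and the linear tuning model is fitted, so the KF baseline
    can be run on the same data.
    """
    train = generate_states(TaskScenario(n_trials=train_trials, seed=seed))
    test = generate_states(TaskScenario(n_trials=test_trials, seed=seed + 10_000))
    F, q_mean, Q, W = fit_transition(train.states)
    model = StateSpaceModel(F=F, q_mean=q_mean, Q=Q, W=W)

    g_train = generate_pseudo_observations(
        train.states, residual_std, np.random.default_rng(np.random.SeedSequence([seed, 7]))
    )
    g_test = generate_pseudo_observations(
        test.states, residual_std, np.random.default_rng(np.random.SeedSequence([seed, 8]))
    )
    r_mean, R, V = estimate_residue_information(g_train - train.states)

    tuning_fit = None
    if with_firing:
        tuning = TuningSpec(m=32, mode=tuning_mode, seed=seed + 1).materialize()
        train.firing = generate_firing(
            train.states, tuning, np.random.default_rng(np.random.SeedSequence([seed, 9]))
        )
        test.firing = generate_firing(
            test.states, tuning, np.random.default_rng(np.random.SeedSequence([seed, 10]))
        )
        tuning_fit = fit_linear_tuning(train.states, train.firing)

    return SimpleNamespace(
        model=model,
        train=train,
        test=test,
        g_train=g_train,
        g_test=g_test,
        r_mean=r_mean,
        R=R,
        V=V,
        tuning=tuning_fit,
        residual_std=residual_std,
    )


@pytest.fixture
def decoding_problem():
    """Factory fixture: seeded synthetic decoding problems."""
    return build_decoding_problem
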