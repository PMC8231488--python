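"""Per-step recursions: prediction, NIF/NMCIF updates, KF baseline, full runs."""

import numpy as np
import pytest

from conftest import make_spd
from nmcif.correntropy import FixedPointSettings, KernelSpec
from nmcif.filters import (
    DecoderSpec,
    FilterState,
    InfoMatrixVariantConfig,
    PriorState,
    asymptotic_info_constant,
    kf_baseline_step,
    nif_update,
    nmcif_update,
    predict,
    run_filter,
)
from nmcif.state_space import StateSpaceModel, LinearTuningModel

INF = float("inf")


def _model(F, Q):
    F = np.atleast_2d(np.asarray(F, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    return StateSpaceModel(F=F, q_mean=np.zeros(F.shape[0]), Q=Q, W=np.linalg.inv(Q))


class TestPredict:
    def test_scalar_closed_form(self):
        prior = predict(FilterState([0.0], [[1.0]]), _model([[1.0]], [[1.0]]))
        assert prior.chi_bar[0, 0] == pytest.approx(0.5)

    def test_total_initial_uncertainty_stays_finite(self, rng):
        model = _model(make_spd(rng, 2) * 0.3, make_spd(rng, 2))
        prior = predict(FilterState(np.zeros(2), np.zeros((2, 2))), model)
        assert np.all(np.isfinite(prior.chi_bar))
        assert np.all(np.linalg.eigvalsh(prior.chi_bar) >= -1e-12)

    def test_matches_inversion_lemma_form(self, rng):
        """Information prediction equals (F chi^-1 F' + Q)^-1 by direct inversion."""
        for _ in range(10):
            F = rng.normal(size=(3, 3)) * 0.4
            Q = make_spd(rng, 3)
            chi = make_spd(rng, 3)
            prior = predict(FilterState(rng.normal(size=3), chi), _model(F, Q))
            oracle = np.linalg.inv(F @ np.linalg.inv(chi) @ F.T + Q)
            assert np.allclose(prior.chi_bar, oracle, atol=1e-9)


class TestNifUpdate:
    def test_uninformative_observation(self, rng):
        prior = PriorState(rng.normal(size=2), make_spd(rng, 2))
        post = nif_update(prior, rng.normal(size=2), np.zeros((2, 2)))
        assert np.allclose(post.x_hat, prior.x_bar)
        assert np.allclose(post.chi_hat, prior.chi_bar)

    def test_uninformative_prior(self, rng):
        g_y = rng.normal(size=2)
        prior = PriorState(rng.normal(size=2), 1e-10 * np.eye(2))
        post = nif_update(prior, g_y, make_spd(rng, 2))
        assert np.allclose(post.x_hat, g_y, atol=1e-8)

    def test_equals_covariance_kalman_filter(self, decoding_problem):
        """Information/covariance duality: NIF trajectory equals a
        covariance-form KF on the identity pseudo-observation model."""
        prob = decoding_problem(5, test_trials=30)
        T = len(prob.test)
        assert T >= 500
        model = prob.model
        Q = np.linalg.inv(model.W)  # exact inverse pair for the duality
        R = np.linalg.inv(prob.V)
        x_info = prob.test.states[0].copy()
        chi = np.eye(2)
        x_cov = x_info.copy()
        P = np.eye(2)
        max_diff = 0.0
        for k in range(T):
            prior = predict(FilterState(x_info, chi), model)
            post = nif_update(prior, prob.g_test[k], prob.V)
            x_info, chi = post.x_hat, post.chi_hat
            # covariance-form oracle
            x_pred = model.F @ x_cov
            P_pred = model.F @ P @ model.F.T + Q
            K = np.linalg.solve(P_pred + R, P_pred).T
            x_cov = x_pred + K @ (prob.g_test[k] - x_pred)
            P = (np.eye(2) - K) @ P_pred
            max_diff = max(max_diff, np.max(np.abs(x_info - x_cov)))
        assert max_diff < 1e-8


class TestNmcifUpdate:
    def test_infinite_bandwidth_equals_nif(self, rng):
        chi, V = make_spd(rng, 2), make_spd(rng, 2)
        prior = PriorState(rng.normal(size=2), chi)
        g_y = rng.normal(size=2)
        nif = nif_update(prior, g_y, V)
        mcc, fp = nmcif_update(prior, g_y, V, KernelSpec(INF))
        assert np.allclose(mcc.x_hat, nif.x_hat, atol=1e-10)
        assert np.allclose(mcc.chi_hat, nif.chi_hat, atol=1e-8)
        assert fp.iterations == 1

    def test_variant_a_infinite_bandwidth_limit(self):
        assert asymptotic_info_constant(1e8, 1.0) == pytest.approx(1.0, rel=1e-10)
        assert asymptotic_info_constant(INF, 0.5) == pytest.approx(4.0)

    @pytest.mark.parametrize("sigma,theta", [(1.0, 1.0), (2.0, 1.0), (5.0, 0.5)])
    def test_variant_a_constant_matches_quadrature(self, sigma, theta):
        """Gauss-Hermite oracle for c = (E[phi'])^2 / E[phi^2] under N(0, theta^2)."""
        nodes, weights = np.polynomial.hermite.hermgauss(120)
        e = np.sqrt(2.0) * theta * nodes
        norm = weights / np.sqrt(np.pi)
        phi_prime = np.exp(-(e**2) / (2 * sigma**2)) * (1 - e**2 / sigma**2)
        phi_sq = (e * np.exp(-(e**2) / (2 * sigma**2))) ** 2
        oracle = np.sum(norm * phi_prime) ** 2 / np.sum(norm * phi_sq)
        assert asymptotic_info_constant(sigma, theta) == pytest.approx(oracle, abs=1e-8)

    def test_variant_a_requires_theta(self):
        with pytest.raises(ValueError):
            InfoMatrixVariantConfig(variant="asymptotic_A", theta=None)

    def test_variant_a_posterior_scales_mtm(self, rng):
        chi, V = make_spd(rng, 2), make_spd(rng, 2)
        prior = PriorState(rng.normal(size=2), chi)
        cfg = InfoMatrixVariantConfig(variant="asymptotic_A", theta=1.0)
        post, _ = nmcif_update(prior, rng.normal(size=2), V, KernelSpec(1e8), info_cfg=cfg)
        assert np.allclose(post.chi_hat, chi + V, rtol=1e-6)


class TestKalmanBaseline:
    def test_identity_tuning_matches_nif(self, rng):
        """With H = I and R_obs = V^-1, the KF and NIF trajectories coincide."""
        prob_seed = 17
        from conftest import build_decoding_problem

        prob = build_decoding_problem(prob_seed, test_trials=10)
        model = StateSpaceModel(
            F=prob.model.F,
            q_mean=prob.model.q_mean,
            Q=np.linalg.inv(prob.model.W),
            W=prob.model.W,
        )
        R = np.linalg.inv(prob.V)
        tuning = LinearTuningModel(H=np.eye(2), r_obs_mean=np.zeros(2), R_obs=R)
        x0 = prob.test.states[0]
        mean, cov = x0.copy(), np.eye(2)
        state = FilterState(x0.copy(), np.eye(2))
        for k in range(min(len(prob.test), 200)):
            mean, cov = kf_baseline_step(mean, cov, prob.g_test[k], model, tuning)
            state = nif_update(predict(state, model), prob.g_test[k], prob.V)
            assert np.max(np.abs(mean - state.x_hat)) < 1e-8

    def test_huge_noise_keeps_prior(self, rng):
        model = _model(np.eye(2) * 0.9, np.eye(2) * 0.01)
        tuning = LinearTuningModel(H=np.eye(2), r_obs_mean=np.zeros(2), R_obs=1e12 * np.eye(2))
        mean0 = np.array([1.0, -1.0])
        mean, cov = kf_baseline_step(mean0, np.eye(2), np.array([100.0, 100.0]), model, tuning)
        assert np.allclose(mean, model.F @ mean0, atol=1e-6)

    def test_converges_to_fixed_state_with_exact_observations(self):
        """Deterministic oracle: zero process noise and exact linear
        observations drive the mean to the true constant state."""
        x_true = np.array([0.7, -0.4])
        model = _model(np.eye(2), 1e-12 * np.eye(2))
        H = np.array([[1.0, 0.3], [0.0, 1.0], [0.5, 0.5]])
        tuning = LinearTuningModel(H=H, r_obs_mean=np.zeros(3), R_obs=1e-6 * np.eye(3))
        mean, cov = np.zeros(2), np.eye(2)
        for _ in range(50):
            mean, cov = kf_baseline_step(mean, cov, H @ x_true, model, tuning)
        assert np.allclose(mean, x_true, atol=1e-5)


class TestRunFilter:
    def test_empty_trajectory(self, decoding_problem):
        from nmcif.state_space import TrialTrajectory

        prob = decoding_problem(3, test_trials=1)
        empty = TrialTrajectory(times=np.zeros(0), states=np.zeros((0, 2)))
        result = run_filter(empty, prob.model, DecoderSpec(kind="nif"), pseudo_obs=np.zeros((0, 2)), V=prob.V)
        assert len(result) == 0

    def test_sigma_inf_run_identical_to_nif(self, decoding_problem):
        prob = decoding_problem(23)
        common = dict(pseudo_obs=prob.g_test, V=prob.V, r_mean=prob.r_mean)
        nif = run_filter(prob.test, prob.model, DecoderSpec(kind="nif"), **common)
        mcc = run_filter(
            prob.test, prob.model, DecoderSpec(kind="nmcif_b", kernel=KernelSpec(INF)), **common
        )
        assert np.allclose(nif.estimates, mcc.estimates, atol=1e-9)
        assert np.all(mcc.iterations == 1)

    def test_nif_forgets_initial_information(self, decoding_problem):
        """NIF estimates after 20 steps are invariant to the (tiny) initial
        information scale."""
        prob = decoding_problem(29)
        runs = [
            run_filter(
                prob.test,
                prob.model,
                DecoderSpec(kind="nif"),
                pseudo_obs=prob.g_test,
                V=prob.V,
                init_info=scale,
            )
            for scale in (1e-6, 1e-8)
        ]
        assert np.max(np.abs(runs[0].estimates[20:] - runs[1].estimates[20:])) < 1e-4

    def test_bad_init_recovery_faster_than_kf(self, decoding_problem):
        """With a [3, 3] initial offset, the information-type filter re-enters
        the 0.2-neighborhood of its well-initialized trajectory before the KF
        does (deviated-initialization behavior)."""
        prob = decoding_problem(41, with_firing=True)
        offset = np.array([3.0, 3.0])
        x0 = prob.test.states[0]

        def steps_to_ball(spec, **kwargs):
            well = run_filter(prob.test, prob.model, spec, init_mean=x0, **kwargs)
            bad = run_filter(prob.test, prob.model, spec, init_mean=x0 + offset, **kwargs)
            dist = np.linalg.norm(well.estimates - bad.estimates, axis=1)
            hits = np.nonzero(dist < 0.2)[0]
            return hits[0] if hits.size else len(dist)

        nmcif_steps = steps_to_ball(
            DecoderSpec(kind="nmcif_b", kernel=KernelSpec(2.0)),
            pseudo_obs=prob.g_test,
            V=prob.V,
            init_info=1e-6,
        )
        kf_steps = steps_to_ball(DecoderSpec(kind="kf"), tuning=prob.tuning, init_cov=1.0)
        assert nmcif_steps < kf_steps

    def test_information_matrix_stays_psd(self, decoding_problem):
        """Posterior information (and KF covariance) remain PSD along 100
        seeded trajectories for every decoder."""
        from conftest import build_decoding_problem
        from nmcif.filters import FilterState, nif_update, nmcif_update, predict

        for seed in range(100):
            prob = build_decoding_problem(seed, test_trials=2, train_trials=8)
            state_b = FilterState(prob.test.states[0], 1e-6 * np.eye(2))
            state_a = FilterState(prob.test.states[0], 1e-6 * np.eye(2))
            state_n = FilterState(prob.test.states[0], 1e-6 * np.eye(2))
            cfg_a = InfoMatrixVariantConfig(variant="asymptotic_A", theta=1.0)
            for k in range(min(len(prob.test), 30)):
                g = prob.g_test[k]
                state_n = nif_update(predict(state_n, prob.model), g, prob.V)
                state_b, _ = nmcif_update(predict(state_b, prob.model), g, prob.V, KernelSpec(2.0))
                state_a, _ = nmcif_update(
                    predict(state_a, prob.model), g, prob.V, KernelSpec(2.0), info_cfg=cfg_a
                )
                for st in (state_n, state_b, state_a):
                    assert np.min(np.linalg.eigvalsh(st.chi_hat)) >= -1e-9

    def test_robustness_direction_under_contamination(self, decoding_problem):
        """Shot-contaminated pseudo-observations: the correntropy filter beats
        the NIF in nearly all replicates (heavy-tailed-noise behavior)."""
        from nmcif.evaluation import mse_2d
        from nmcif.synthetic import ContaminationSpec, contaminate
        from conftest import build_decoding_problem

        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            prob = build_decoding_problem(seed + 300, test_trials=8)
            spec_c = ContaminationSpec(fraction=0.033, magnitude=100.0, seed=seed + 77)
            g_cont, _ = contaminate(prob.g_test, spec_c, baseline_var=np.diag(prob.R))
            common = dict(pseudo_obs=g_cont, V=prob.V, r_mean=prob.r_mean)
            nif = run_filter(prob.test, prob.model, DecoderSpec(kind="nif"), **common)
            best = min(
                mse_2d(
                    run_filter(
                        prob.test,
                        prob.model,
                        DecoderSpec(kind="nmcif_b", kernel=KernelSpec(s)),
                        **common,
                    ).estimates,
                    prob.test.states,
                )
                for s in (1.0, 2.0, 5.0)
            )
            if best < mse_2d(nif.estimates, prob.test.states):
                wins += 1
        assert wins >= 0.9 * n_rep

    def test_single_outlier_influence_bounded(self, rng):
        """One gross outlier barely moves the correntropy posterior, moves the
        NIF posterior linearly, and its influence redescends with magnitude."""
        prior = PriorState(np.zeros(2), np.eye(2))
        V = np.eye(2)
        g_clean = np.array([0.3, -0.2])
        shifts_nmcif, shifts_nif = [], []
        for magnitude in (2.0, 20.0, 1e3, 1e6):
            g_out = g_clean + magnitude
            post_clean, _ = nmcif_update(prior, g_clean, V, KernelSpec(2.0))
            post_out, _ = nmcif_update(prior, g_out, V, KernelSpec(2.0))
            shifts_nmcif.append(np.linalg.norm(post_out.x_hat - post_clean.x_hat))
            nif_clean = nif_update(prior, g_clean, V)
            nif_out = nif_update(prior, g_out, V)
            shifts_nif.append(np.linalg.norm(nif_out.x_hat - nif_clean.x_hat))
        assert shifts_nmcif[-1] < shifts_nif[-1]
        assert shifts_nif[-1] > 1e5  # linear growth for the non-robust update
        # redescending influence: the shift shrinks once the outlier passes sigma
        assert shifts_nmcif[-1] <= shifts_nmcif[1] + 1e-9
        assert shifts_nmcif[-1] < 1.0
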