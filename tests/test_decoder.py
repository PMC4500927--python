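import numpy as np
import pytest

from bcisim import decoder as dec
from bcisim.decoder import (
    DecoderState,
    SingularFitError,
    TrajectoryModel,
    fit_trajectory_model,
    init_state,
    measurement_fn,
    measurement_jacobian,
    predict,
    update,
)
from bcisim.encoder import EnsembleParams, sample_ensemble, sample_population
from bcisim.experiments import ReachTask

from helpers import LinearMeasurement, textbook_kf_update

DT = 0.03


def constant_velocity_traces(rng, n_traces=20, n_steps=30):
    """States evolving by an exactly known kinematic transition with a
    static goal: pos += dt*vel, vel += dt*acc, acc and goal constant."""
    A = np.eye(12)
    A[0:3, 3:6] = DT * np.eye(3)
    A[3:6, 6:9] = DT * np.eye(3)
    traces = []
    for _ in range(n_traces):
        s = np.concatenate([rng.uniform(-20, 20, 3), rng.uniform(-30, 30, 3),
                            rng.uniform(-50, 50, 3), rng.uniform(-20, 20, 3)])
        tr = [s]
        for _ in range(n_steps - 1):
            s = A @ s
            tr.append(s)
        traces.append(np.array(tr))
    return A, traces


class TestTrajectoryModelFit:
    def test_recovers_known_kinematic_transition(self, rng):
        A_true, traces = constant_velocity_traces(rng)
        tm = fit_trajectory_model(traces)
        np.testing.assert_allclose(tm.A, A_true, atol=1e-6)
        assert np.abs(tm.W).max() < 1e-10

    def test_goal_block_identity_for_static_goals(self, rng):
        _, traces = constant_velocity_traces(rng)
        tm = fit_trajectory_model(traces)
        np.testing.assert_allclose(tm.A[9:12, 9:12], np.eye(3), atol=1e-6)
        np.testing.assert_allclose(tm.A[9:12, 0:9], 0, atol=1e-6)

    def test_single_constant_trace_acts_as_identity_on_it(self):
        s = np.arange(12, dtype=float) + 1.0
        tm = fit_trajectory_model([np.tile(s, (20, 1))])
        np.testing.assert_allclose(tm.A @ s, s, atol=1e-5)
        assert np.abs(tm.W).max() < 1e-10

    def test_too_little_data_rejected(self):
        with pytest.raises(SingularFitError):
            fit_trajectory_model([np.zeros((3, 12))])


class TestInitialBelief:
    task = ReachTask(start_pos=(1.0, -2.0, 3.0), target_pos=(0.0, 0.0, 0.0),
                     max_time=3.0)

    def test_mean_is_known_start_and_zero_kinematics(self):
        ds = init_state(self.task)
        np.testing.assert_allclose(ds.mean[0:3], [1.0, -2.0, 3.0])
        assert not ds.mean[3:9].any()

    def test_covariance_encodes_known_start_unknown_goal(self):
        ds = init_state(self.task)
        np.testing.assert_allclose(np.diag(ds.cov),
                                   [0.001] * 9 + [1000.0] * 3)
        assert not (ds.cov - np.diag(np.diag(ds.cov))).any()

    def test_goal_prior_mean_configurable(self):
        ds = init_state(self.task, goal_prior_mean=(1.0, 2.0, 3.0))
        np.testing.assert_allclose(ds.mean[9:12], [1, 2, 3])


class TestPredict:
    def test_identity_dynamics_no_noise_is_noop(self):
        ds = DecoderState(mean=np.arange(12.0), cov=np.eye(12))
        out = predict(ds, TrajectoryModel(A=np.eye(12), W=np.zeros((12, 12))))
        np.testing.assert_allclose(out.mean, ds.mean)
        np.testing.assert_allclose(out.cov, ds.cov)

    def test_pure_process_noise(self, rng):
        W = rng.normal(size=(12, 12))
        W = W @ W.T
        ds = DecoderState(mean=np.zeros(12), cov=np.zeros((12, 12)))
        out = predict(ds, TrajectoryModel(A=rng.normal(size=(12, 12)), W=W))
        np.testing.assert_allclose(out.cov, 0.5 * (W + W.T), atol=1e-12)

    def test_covariance_stays_psd(self, rng):
        for _ in range(10):
            L = rng.normal(size=(12, 12))
            ds = DecoderState(mean=rng.normal(size=12), cov=L @ L.T)
            Wh = rng.normal(size=(12, 12)) * 0.1
            tm = TrajectoryModel(A=rng.normal(size=(12, 12)), W=Wh @ Wh.T)
            out = predict(ds, tm)
            assert np.linalg.eigvalsh(out.cov).min() > -1e-9


class TestMeasurementModel:
    def test_baseline_rates_at_rest_state(self):
        ens = sample_ensemble(6, 0, seed=1)
        rest = np.zeros(12)
        rates = measurement_fn(rest, ens)
        from bcisim.encoder import saturate
        for r, sp in zip(rates, ens.neurons):
            if sp.kind in ("position", "velocity"):
                assert r == pytest.approx(saturate(sp.tuning.f_base))

    def test_gaussian_peak_through_saturation(self):
        ens = sample_population("goal_gaussian", 3, q_std=15.0, seed=2)
        from bcisim.encoder import saturate
        sp = ens.neurons[0]
        state = np.zeros(12)
        state[9:12] = sp.q_pos
        rates = measurement_fn(state, ens)
        assert rates[0] == pytest.approx(saturate(sp.f_min + sp.f_amp))

    def test_structural_sparsity_velocity_only(self):
        ens = sample_population("velocity", 5, seed=3)
        H = measurement_jacobian(np.zeros(12), ens)
        assert not H[:, 0:3].any() and not H[:, 6:9].any() and not H[:, 9:12].any()
        assert H[:, 3:6].any()

    def test_gaussian_gradient_vanishes_at_peak(self):
        ens = sample_population("goal_gaussian", 1, q_std=20.0, seed=4)
        state = np.zeros(12)
        state[9:12] = ens.neurons[0].q_pos
        H = measurement_jacobian(state, ens)
        np.testing.assert_allclose(H[0, 9:12], 0, atol=1e-12)

    def test_jacobian_matches_finite_differences(self, mixed_ensemble, rng):
        state = rng.normal(scale=10, size=12)
        H = measurement_jacobian(state, mixed_ensemble)
        h = 1e-4
        for j in range(12):
            dp = state.copy(); dp[j] += h
            dm = state.copy(); dm[j] -= h
            fd = (measurement_fn(dp, mixed_ensemble)
                  - measurement_fn(dm, mixed_ensemble)) / (2 * h)
            scale = np.maximum(np.abs(fd), 1e-3)
            assert np.max(np.abs(H[:, j] - fd) / scale) < 1e-4


class TestUpdate:
    def test_zero_innovation_keeps_mean(self, mixed_ensemble):
        ds = DecoderState(mean=np.zeros(12), cov=np.eye(12))
        obs = measurement_fn(ds.mean, mixed_ensemble)
        out = update(ds, obs, mixed_ensemble, DT)
        np.testing.assert_allclose(out.mean, ds.mean, atol=1e-9)
        assert np.all(np.diag(out.cov) <= np.diag(ds.cov) + 1e-12)

    def test_equals_textbook_kf_in_linear_limit(self, rng):
        H = rng.normal(size=(8, 12))
        R = np.diag(rng.uniform(0.5, 2.0, 8))
        model = LinearMeasurement(H, np.diag(R))
        L = rng.normal(size=(12, 12)) * 0.5
        ds = DecoderState(mean=rng.normal(size=12), cov=L @ L.T + 0.1 * np.eye(12))
        observed = rng.normal(size=8)
        out = update(ds, observed, model, DT)
        m_ref, P_ref = textbook_kf_update(ds.mean, ds.cov, H, R, observed)
        np.testing.assert_allclose(out.mean, m_ref, atol=1e-8)
        np.testing.assert_allclose(out.cov, 0.5 * (P_ref + P_ref.T), atol=1e-8)

    def test_static_velocity_estimate_is_calibrated(self):
        """200 noisy updates on a static state: decoded velocity lands within
        2 posterior standard deviations of the truth."""
        ens = sample_population("velocity", 50,
                                params=EnsembleParams(poisson_fraction=1.0), seed=8)
        rng = np.random.default_rng(123)
        truth = np.zeros(12)
        truth[3:6] = [12.0, -5.0, 7.0]
        tm = TrajectoryModel(A=np.eye(12), W=np.diag([1e-4] * 12))
        ds = DecoderState(mean=np.zeros(12),
                          cov=np.diag([1e-3] * 3 + [100.0] * 3 + [1e-3] * 6))
        for _ in range(200):
            expected = ens.expected_rates(truth)
            obs = ens.sample_rates(expected, DT, rng)
            ds = predict(ds, tm)
            ds = update(ds, obs, ens, DT)
        err = ds.mean[3:6] - truth[3:6]
        sd = np.sqrt(np.diag(ds.cov)[3:6])
        assert np.all(np.abs(err) < 2.0 * sd)

    def test_covariance_psd_through_many_cycles(self, trajectory_model):
        ens = sample_ensemble(6, 4, seed=10)
        rng = np.random.default_rng(7)
        task = ReachTask(start_pos=(0.0, -25.0, -37.5), target_pos=(0.0, 0.0, 0.0),
                         max_time=3.0)
        ds = init_state(task)
        state = np.zeros(12)
        for k in range(1000):
            obs = ens.sample_rates(ens.expected_rates(state), DT, rng)
            ds = predict(ds, trajectory_model)
            ds = update(ds, obs, ens, DT)
            assert np.allclose(ds.cov, ds.cov.T, atol=1e-9)
            if k % 100 == 0:
                assert np.linalg.eigvalsh(ds.cov).min() > -1e-9

    def test_goal_covariance_contracts_with_goal_neurons(self):
        """With Gaussian goal neurons observing a static goal, the goal-block
        covariance trace decreases from its uninformative initialization."""
        ens = sample_population("goal_gaussian", 10, q_std=20.0, seed=11)
        rng = np.random.default_rng(3)
        task = ReachTask(start_pos=(0.0, -25.0, -37.5), target_pos=(5.0, 5.0, 5.0),
                         max_time=3.0)
        tm = TrajectoryModel(A=np.eye(12), W=np.diag([1e-6] * 12))
        ds = init_state(task)
        state = np.zeros(12)
        state[9:12] = task.target_pos
        traces = [np.trace(ds.cov[9:12, 9:12])]
        for _ in range(100):
            obs = ens.sample_rates(ens.expected_rates(state), DT, rng)
            ds = predict(ds, tm)
            ds = update(ds, obs, ens, DT)
            traces.append(np.trace(ds.cov[9:12, 9:12]))
        diffs = np.diff(traces)
        assert traces[-1] < traces[0]
        assert np.all(diffs <= 1e-6)

    def test_observation_length_mismatch_rejected(self, mixed_ensemble):
        ds = DecoderState(mean=np.zeros(12), cov=np.eye(12))
        with pytest.raises(ValueError):
            update(ds, np.zeros(3), mixed_ensemble, DT)


class TestSerialization:
    def test_trajectory_model_roundtrip(self, trajectory_model):
        clone = TrajectoryModel.from_dict(trajectory_model.to_dict())
        np.testing.assert_allclose(clone.A, trajectory_model.A)
        np.testing.assert_allclose(clone.W, trajectory_model.W)

    def test_decoder_state_roundtrip(self):
        ds = DecoderState(mean=np.arange(12.0), cov=np.eye(12) * 2.0)
        clone = DecoderState.from_dict(ds.to_dict())
        np.testing.assert_allclose(clone.mean, ds.mean)
        np.testing.assert_allclose(clone.cov, ds.cov)
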