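"""Pose-fusion EKF: initialization, kinematics, Jacobians, filtering, tuning."""

import math

import numpy as np
import pytest

from gaitaccel import (
    ImuSeries,
    NoiseTuningParams,
    innovation_log_likelihood,
    run_pose_estimation,
    tune_noise_parameters,
)
from gaitaccel.core import EulerPoseSeries, rotation_matrix
from gaitaccel.ekf import (
    adaptive_observation_noise,
    adaptive_process_noise,
    compute_jacobians,
    ekf_step,
    initial_tilt_from_accel,
    observation_model,
    state_transition,
    tilt_compensate_and_yaw,
    tilt_rotation,
)
from gaitaccel.errors import (
    ConfigurationError,
    DegenerateInputError,
    InvalidInputError,
    NumericalError,
)


def make_static_imu(duration=10.0, dt=0.01, accel=(0.0, 0.0, 9.8), mag=(1.0, 0.0, 0.0)):
    n = int(round(duration / dt)) + 1
    return ImuSeries(
        dt=dt,
        gyro=np.zeros((n, 3)),
        accel=np.tile(accel, (n, 1)),
        mag=np.tile(mag, (n, 1)),
    )


class TestInitialization:
    def test_level_pose(self):
        assert initial_tilt_from_accel((0, 0, 9.8)) == (0.0, 0.0)

    def test_thirty_degree_roll(self):
        roll, pitch = initial_tilt_from_accel((0.0, 4.9, 8.4870))
        assert abs(math.degrees(roll) - 30.0) < 0.01
        assert abs(pitch) < 1e-6

    def test_thirty_degree_pitch(self):
        roll, pitch = initial_tilt_from_accel((-4.9, 0.0, 8.4870))
        assert abs(math.degrees(pitch) - 30.0) < 0.01
        assert abs(roll) < 1e-6

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            initial_tilt_from_accel((0.0, 0.0, 0.0))

    def test_tilt_matrix_matches_component_form(self, rng):
        # the de-tilt matrix, written out entry by entry
        for roll, pitch in rng.uniform(-1.5, 1.5, size=(20, 2)):
            ct, st_ = np.cos(pitch), np.sin(pitch)
            cr, sr = np.cos(roll), np.sin(roll)
            expected = np.array(
                [
                    [ct, sr * st_, cr * st_],
                    [0.0, cr, -sr],
                    [-st_, sr * ct, cr * ct],
                ]
            )
            np.testing.assert_allclose(tilt_rotation(roll, pitch), expected, atol=1e-15)

    def test_heading_examples(self):
        m_c, yaw = tilt_compensate_and_yaw((1.0, 0.0, 0.0), 0.0, 0.0)
        np.testing.assert_allclose(m_c, (1, 0, 0))
        assert yaw == 0.0
        _, yaw = tilt_compensate_and_yaw((0.0, 1.0, 0.0), 0.0, 0.0)
        assert abs(math.degrees(yaw) + 90.0) < 1e-12

    def test_tilt_compensation_preserves_norm(self, rng):
        for _ in range(200):
            m = rng.normal(size=3)
            roll, pitch = rng.uniform(-1.5, 1.5, 2)
            m_c, _ = tilt_compensate_and_yaw(m, roll, pitch)
            assert abs(np.linalg.norm(m_c) - np.linalg.norm(m)) <= 1e-12

    def test_heading_recovers_true_yaw_with_true_tilt(self, rng):
        # de-tilting with the true attitude reduces heading to pure yaw
        m_ref = np.array([1.0, 0.0, 0.0])
        for roll, pitch, yaw in rng.uniform(-1.2, 1.2, size=(50, 3)):
            m_sensor = rotation_matrix(roll, pitch, yaw).T @ m_ref
            _, psi = tilt_compensate_and_yaw(m_sensor, roll, pitch)
            assert abs(psi - yaw) < 1e-10


class TestKinematics:
    def test_zero_attitude_axis_swap(self):
        out = state_transition((0.0, 0.0, 0.0), (0.1, 0.2, 0.3), 0.01)
        np.testing.assert_allclose(out, [0.3 * 0.01, 0.2 * 0.01, 0.1 * 0.01])

    def test_zero_gyro_fixed_point(self):
        state = np.array([0.4, -0.2, 0.9])
        np.testing.assert_allclose(state_transition(state, (0, 0, 0), 0.01), state)

    def test_constant_roll_rate_integrates(self):
        state = np.zeros(3)
        w = (math.radians(10.0), 0.0, 0.0)
        for _ in range(100):
            state = state_transition(state, w, 0.01)
        assert abs(math.degrees(state[2]) - 10.0) < 0.05

    def test_observation_examples(self):
        np.testing.assert_allclose(observation_model((0, 0, 0)), [0, 0, 0, 9.8])
        np.testing.assert_allclose(observation_model((1.0, 0, 0)), [1.0, 0, 0, 9.8])
        out = observation_model((0.0, math.radians(30), 0.0))
        np.testing.assert_allclose(out, [0.0, -4.9, 0.0, 9.8 * math.cos(math.radians(30))],
                                   atol=1e-9)


class TestJacobians:
    def test_identity_at_zero_gyro(self):
        f, h = compute_jacobians((0.1, 0.2, 0.3), (0, 0, 0), 0.01)
        np.testing.assert_allclose(f, np.eye(3))
        np.testing.assert_allclose(h[0], [1.0, 0.0, 0.0])

    def test_matches_finite_differences(self, rng):
        # central differences as the independent oracle
        dt, g, eps = 0.01, 9.8, 1e-6
        worst = 0.0
        for _ in range(200):
            state = rng.uniform(-1.2, 1.2, 3)
            gyro = rng.uniform(-5, 5, 3)
            f, h = compute_jacobians(state, gyro, dt, g)
            f_num = np.empty((3, 3))
            h_num = np.empty((4, 3))
            for j in range(3):
                dp = np.zeros(3)
                dp[j] = eps
                f_num[:, j] = (
                    state_transition(state + dp, gyro, dt)
                    - state_transition(state - dp, gyro, dt)
                ) / (2 * eps)
                h_num[:, j] = (
                    observation_model(state + dp, g) - observation_model(state - dp, g)
                ) / (2 * eps)
            worst = max(worst, np.max(np.abs(f - f_num)), np.max(np.abs(h - h_num)))
        assert worst <= 1e-5


class TestAdaptiveNoise:
    def test_process_noise_floor(self):
        q = adaptive_process_noise((0, 0, 0), NoiseTuningParams(a=0.1, b=0.01))
        np.testing.assert_allclose(q, 0.01 * np.eye(3))

    def test_process_noise_example(self):
        q = adaptive_process_noise((1, 2, 2), NoiseTuningParams(a=0.1, b=0.01))
        np.testing.assert_allclose(np.diag(q), 0.91)

    def test_process_noise_quadratic_scaling(self):
        p = NoiseTuningParams(a=0.03, b=0.002)
        q1 = adaptive_process_noise((1.0, -2.0, 0.5), p)[0, 0] - p.b
        q2 = adaptive_process_noise((2.0, -4.0, 1.0), p)[0, 0] - p.b
        assert abs(q2 - 4 * q1) < 1e-12

    def test_observation_noise_rest(self):
        p = NoiseTuningParams(c=0.1, d=0.02, e=0.5, f=0.1, mag_norm_ref=1.0)
        r = adaptive_observation_noise((0, 0, 9.8), (1, 0, 0), p)
        assert r[0, 0] == pytest.approx(0.02)
        assert r[1, 1] == pytest.approx(0.1)

    def test_observation_noise_example(self):
        p = NoiseTuningParams(c=0.1, d=0.02, e=0.5, f=0.1, mag_norm_ref=1.0)
        r = adaptive_observation_noise((1, 0, 9.8), (1, 0, 0), p)
        assert r[1, 1] == pytest.approx(0.6)

    def test_floors_enforced(self):
        with pytest.raises(ConfigurationError):
            NoiseTuningParams(b=0.0)
        with pytest.raises(ConfigurationError):
            NoiseTuningParams(a=-1.0)
        # negative disturbance term is floored, not propagated
        p = NoiseTuningParams(c=10.0, d=1e-6, mag_norm_ref=2.0)
        r = adaptive_observation_noise((0, 0, 9.8), (1, 0, 0), p)
        assert r[0, 0] >= 1e-9


class TestEkfStep:
    def test_zero_innovation_keeps_prediction(self):
        params = NoiseTuningParams(mag_norm_ref=1.0)
        state = np.array([0.1, 0.05, -0.2])
        gyro = np.array([0.3, -0.1, 0.2])
        pred = state_transition(state, gyro, 0.01)
        y = observation_model(pred)
        new, P, V, B, K = ekf_step(state, 0.01 * np.eye(3), y, gyro, 0.01, params)
        np.testing.assert_allclose(V, 0.0, atol=1e-12)
        np.testing.assert_allclose(new, pred, atol=1e-12)

    def test_prediction_covariance_inflates_by_q(self):
        # zero gyro -> f = I, so P- = P + Q exactly
        params = NoiseTuningParams(a=0.0, b=0.04, mag_norm_ref=1.0)
        P = np.diag([0.01, 0.02, 0.03])
        state = np.zeros(3)
        y = observation_model(state)
        # huge R isolates the prediction: posterior ~ prior
        big = NoiseTuningParams(a=0.0, b=0.04, d=1e9, f=1e9, e=0.0, c=0.0,
                                mag_norm_ref=1.0)
        _, P_new, _, B, _ = ekf_step(state, P, y, np.zeros(3), 0.01, big)
        np.testing.assert_allclose(P_new, P + 0.04 * np.eye(3), atol=1e-6)

    def test_huge_r_freezes_update(self):
        params = NoiseTuningParams(d=1e6, f=1e6, c=0.0, e=0.0, mag_norm_ref=1.0)
        state = np.array([0.2, -0.1, 0.4])
        gyro = np.array([1.0, 0.5, -0.5])
        pred = state_transition(state, gyro, 0.01)
        y = observation_model(pred) + np.array([0.1, 0.5, 0.5, 0.5])
        new, *_ = ekf_step(state, 0.01 * np.eye(3), y, gyro, 0.01, params)
        assert np.max(np.abs(new - pred)) <= 1e-4


class TestRunPoseEstimation:
    def test_static_record_stays_at_zero(self):
        poses = run_pose_estimation(make_static_imu(duration=60.0))
        assert np.max(np.abs(np.degrees(poses.angles))) <= 0.1

    def test_constant_roll_rate_recovered(self):
        # 1 s static calibration, then 2 s of 10 deg/s roll
        dt = 0.01
        n_cal, n_rot = 100, 200
        rate = math.radians(10.0)
        t_rot = dt * np.arange(1, n_rot + 1)
        roll = np.concatenate([np.zeros(n_cal), rate * t_rot])
        n = n_cal + n_rot
        gyro = np.zeros((n, 3))
        gyro[n_cal:, 0] = rate
        R = rotation_matrix(roll, np.zeros(n), np.zeros(n))
        accel = np.einsum("nji,j->ni", R, [0.0, 0.0, 9.8])
        mag = np.einsum("nji,j->ni", R, [1.0, 0.0, 0.0])
        imu = ImuSeries(dt=dt, gyro=gyro, accel=accel, mag=mag)
        poses = run_pose_estimation(imu, calibration_window=1.0)
        assert abs(math.degrees(poses.roll[-1]) - 20.0) < 0.2

    def test_gait_pose_recovery(self, gait_noiseless, gait_poses):
        _, truth = gait_noiseless
        err = np.degrees(gait_poses.angles - truth.poses.angles)
        rmse = np.sqrt(np.mean(err**2, axis=0))
        assert rmse[1] <= 2.0          # pitch
        assert rmse[0] <= 5.0          # roll
        assert rmse[2] <= 5.0          # yaw

    def test_covariances_symmetric_psd(self, gait_poses):
        gait_poses.validate_covariances(tol=1e-9)

    def test_output_aligned_with_input(self, gait_noiseless, gait_poses):
        imu, _ = gait_noiseless
        assert len(gait_poses) == len(imu)
        assert gait_poses.dt == imu.dt

    def test_calibration_window_too_long(self):
        imu = make_static_imu(duration=2.0)
        with pytest.raises(InvalidInputError):
            run_pose_estimation(imu, calibration_window=10.0)

    def test_motion_in_calibration_window_warns(self):
        imu = make_static_imu(duration=6.0)
        imu.gyro[:, 0] = 0.5  # clearly not standing still
        poses = run_pose_estimation(imu, calibration_window=2.0)
        assert any("not static" in w for w in poses.warnings)


class TestLikelihood:
    @staticmethod
    def _series_with(V, B):
        n = len(V) + 1
        Vfull = np.zeros((n, 4))
        Bfull = np.repeat(np.eye(4)[None], n, axis=0)
        Vfull[1:] = V
        Bfull[1:] = B
        return EulerPoseSeries(
            dt=0.01, angles=np.zeros((n, 3)), innovation=Vfull, innovation_cov=Bfull
        )

    def test_closed_form_single_step(self):
        # V = 0, B = I: LL = -(dim/2) ln(2 pi) per step
        rep = innovation_log_likelihood(
            self._series_with(np.zeros((1, 4)), np.eye(4)[None])
        )
        assert rep.ll == pytest.approx(-2.0 * math.log(2 * math.pi))
        assert rep.n_steps == 1

    def test_doubling_b_costs_half_log_two_per_dim(self):
        base = innovation_log_likelihood(
            self._series_with(np.zeros((1, 4)), np.eye(4)[None])
        ).ll
        doubled = innovation_log_likelihood(
            self._series_with(np.zeros((1, 4)), 2.0 * np.eye(4)[None])
        ).ll
        assert base - doubled == pytest.approx(4 * 0.5 * math.log(2.0))

    def test_zero_innovation_is_maximal(self, rng):
        B = np.repeat(np.eye(4)[None], 10, axis=0)
        best = innovation_log_likelihood(self._series_with(np.zeros((10, 4)), B)).ll
        for _ in range(5):
            V = rng.normal(0, 0.5, (10, 4))
            assert innovation_log_likelihood(self._series_with(V, B)).ll < best

    def test_indefinite_b_rejected(self):
        B = -np.eye(4)[None]
        with pytest.raises(NumericalError):
            innovation_log_likelihood(self._series_with(np.zeros((1, 4)), B))


class TestTuning:
    def test_monotone_improvement(self, gait_noisy):
        imu, _ = gait_noisy
        res = tune_noise_parameters(imu, max_evals=80)
        assert res.ll_final >= res.ll_initial
        assert res.n_evaluations <= 80 + 1

    def test_noisier_gyro_prefers_larger_b(self):
        # LL profile over b on quiet-stance records with the observation
        # coefficients matched to the injected noise: the maximizing b grows
        # with (and tracks the scale of) the per-step gyro noise variance
        rng = np.random.default_rng(5)

        def static_noisy(sigma, duration=30.0, dt=0.01):
            n = int(duration / dt) + 1
            return ImuSeries(
                dt=dt,
                gyro=rng.normal(0, sigma, (n, 3)),
                accel=np.tile([0, 0, 9.8], (n, 1)) + rng.normal(0, 0.1, (n, 3)),
                mag=np.tile([1, 0, 0], (n, 1)) + rng.normal(0, 0.01, (n, 3)),
            )

        grid = 10.0 ** np.arange(-10.0, -4.0, 0.25)
        argmax_b = []
        for sigma in (0.005, 0.02):
            imu = static_noisy(sigma)
            lls = []
            for b in grid:
                p = NoiseTuningParams(a=0.0, b=b, c=0.0, d=1e-4, e=0.0, f=0.01)
                lls.append(
                    innovation_log_likelihood(
                        run_pose_estimation(imu, p, calibration_window=2.0)
                    ).ll
                )
            argmax_b.append(grid[int(np.argmax(lls))])
        assert argmax_b[1] > argmax_b[0]
        # the optimum sits near the true per-step variance (sigma * dt)^2
        assert 0.1 * (0.02 * 0.01) ** 2 < argmax_b[1] < 10 * (0.02 * 0.01) ** 2

    def test_noise_robustness_of_default_filter(self, gait_noiseless, gait_poses,
                                                gait_noisy):
        # realistic sensor noise should not blow up pose recovery: roll and
        # pitch stay within 2x of the noiseless errors; yaw, whose noiseless
        # error is pinned near zero by the exact compass, is bounded
        # absolutely by the heading-noise scale
        _, truth_clean = gait_noiseless
        clean = np.sqrt(
            np.mean(np.degrees(gait_poses.angles - truth_clean.poses.angles) ** 2, axis=0)
        )
        imu_n, truth_n = gait_noisy
        poses_n = run_pose_estimation(imu_n)
        noisy = np.sqrt(
            np.mean(np.degrees(poses_n.angles - truth_n.poses.angles) ** 2, axis=0)
        )
        assert noisy[0] <= 2.0 * clean[0]
        assert noisy[1] <= 2.0 * clean[1]
        assert noisy[2] <= 1.0
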