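"""Attitude initialization, the quaternion EKF, and Euler-angle RMSD."""

from dataclasses import replace

import numpy as np
import pytest

from gaitdisp import (ImuRecording, QuaternionSeries, angle_rmsd,
                      ekf_orientation, estimate_gyro_bias,
                      initial_attitude_from_rest)
from gaitdisp import quat
from gaitdisp.orientation import OrientationFilterParams, constant_orientation

FS = 100.0


class TestInitialAttitude:
    def test_level_gives_identity(self):
        f = np.tile([0.0, 0.0, -9.81], (150, 1))
        q0 = initial_attitude_from_rest(f)
        assert np.allclose(q0, [1.0, 0, 0, 0], atol=1e-12)

    @pytest.mark.parametrize("roll_deg", [10.0, -25.0, 3.0])
    def test_pure_roll_recovered(self, roll_deg):
        q_true = quat.from_euler_zyx(0.0, 0.0, np.deg2rad(roll_deg))
        f = quat.rotate_inverse(q_true, np.array([0.0, 0.0, -9.81]))
        q0 = initial_attitude_from_rest(np.tile(f, (150, 1)))
        yaw, pitch, roll = np.rad2deg(quat.to_euler_zyx(q0))
        assert roll == pytest.approx(roll_deg, abs=1e-9)
        assert yaw == pytest.approx(0.0, abs=1e-9)
        assert pitch == pytest.approx(0.0, abs=1e-9)

    def test_moving_subject_rejected(self):
        f = np.tile([0.0, 0.0, -5.0], (150, 1))
        with pytest.raises(ValueError):
            initial_attitude_from_rest(f)


class TestEkf:
    def _static(self, n=400, q0=None):
        q0 = np.array([1.0, 0, 0, 0]) if q0 is None else q0
        f = quat.rotate_inverse(q0, np.array([0.0, 0.0, -9.81]))
        return ImuRecording(np.arange(n) / FS, np.zeros((n, 3)),
                            np.tile(f, (n, 1)), FS), q0

    def test_static_equilibrium_holds_initial_quaternion(self):
        imu, q0 = self._static(q0=quat.from_euler_zyx(0.3, 0.1, -0.2))
        out = ekf_orientation(imu, q0)
        assert np.abs(out.q - q0).max() < 1e-9

    def test_constant_rate_matches_closed_form(self):
        """Gyro-only propagation equals axis-angle integration q0 ⊗ exp(½ωt)."""
        omega = np.array([0.4, -0.7, 0.9])
        n = 500
        t = np.arange(n) / FS
        imu = ImuRecording(t, np.tile(omega, (n, 1)),
                           np.tile([0.0, 0, -9.81], (n, 1)), FS)
        q0 = quat.from_euler_zyx(0.2, -0.1, 0.05)
        out = ekf_orientation(imu, q0, accel_updates=False)
        expected = np.array([quat.multiply(q0, quat.exp_map(omega * ti))
                             for ti in t])
        expected = quat.enforce_sign_continuity(expected)
        # angular error between estimated and closed-form quaternions
        dots = np.abs(np.sum(out.q * expected, axis=1))
        ang = 2 * np.arccos(np.clip(dots, -1, 1))
        assert ang.max() < 1e-6

    def test_outputs_unit_and_sign_continuous(self, default_trial):
        out = ekf_orientation(default_trial.trunk, np.array([1.0, 0, 0, 0]))
        assert np.allclose(np.linalg.norm(out.q, axis=1), 1.0, atol=1e-9)
        assert np.all(np.sum(out.q[1:] * out.q[:-1], axis=1) >= 0)

    def test_deterministic(self, default_trial):
        q0 = np.array([1.0, 0, 0, 0])
        a = ekf_orientation(default_trial.trunk, q0)
        b = ekf_orientation(default_trial.trunk, q0)
        assert np.array_equal(a.q, b.q)

    def test_accel_updates_bound_tilt_error_under_gyro_bias(self):
        """With gravity updates, roll/pitch stay bounded despite a gyro bias;
        unaided yaw drifts."""
        n = 6000
        t = np.arange(n) / FS
        bias = np.deg2rad([0.5, -0.4, 0.45])
        imu = ImuRecording(t, np.tile(bias, (n, 1)),
                           np.tile([0.0, 0, -9.81], (n, 1)), FS)
        q0 = np.array([1.0, 0, 0, 0])
        # static data: the accelerometer can be trusted tightly
        params = OrientationFilterParams(accel_meas_noise=0.1)
        aided = ekf_orientation(imu, q0, params)
        unaided = ekf_orientation(imu, q0, accel_updates=False)

        def tilt_err(series, sl):
            e = np.rad2deg(quat.to_euler_zyx(series.q[sl]))
            return np.abs(e[:, 1:]).max()  # worst pitch/roll, deg

        early, late = slice(2000, 3000), slice(5000, 6000)
        assert tilt_err(aided, late) < 3.0                    # bounded
        assert tilt_err(aided, late) < 1.1 * tilt_err(aided, early) + 0.2
        assert tilt_err(unaided, late) > 1.7 * tilt_err(unaided, early)
        assert tilt_err(unaided, late) > 3 * tilt_err(aided, late)
        yaw_late = np.abs(np.rad2deg(quat.to_euler_zyx(aided.q[late]))[:, 0])
        assert yaw_late.min() > 5.0  # heading still drifts with the bias

    def test_walking_trial_orientation_accuracy(self, default_trial):
        """Roll/pitch RMSD within the published magnitude range; yaw worse."""
        st = default_trial
        rest = slice(0, int(5 * FS))
        bias = estimate_gyro_bias(st.trunk.gyro[rest])
        trunk = replace(st.trunk, gyro=st.trunk.gyro - bias)
        q0 = initial_attitude_from_rest(st.trunk.specific_force[rest])
        est = ekf_orientation(trunk, q0)
        roll, pitch, yaw = angle_rmsd(est, st.truth_quat, trim_s=10.0)
        assert roll <= 1.2 and pitch <= 1.2
        assert yaw > max(roll, pitch)


class TestAngleRmsd:
    def test_identical_series_zero(self, default_trial):
        q = default_trial.truth_quat
        assert angle_rmsd(q, q) == (0.0, 0.0, 0.0)

    def test_constant_yaw_offset(self):
        n = 300
        t = np.arange(n) / FS
        q_ref = constant_orientation(t, quat.from_euler_zyx(0.1, 0.2, -0.1))
        dq = quat.from_euler_zyx(np.deg2rad(2.0), 0.0, 0.0)
        q_est = QuaternionSeries(t, np.array([quat.multiply(dq, qq)
                                              for qq in q_ref.q]))
        roll, pitch, yaw = angle_rmsd(q_est, q_ref)
        assert yaw == pytest.approx(2.0, abs=1e-6)
        assert roll == pytest.approx(0.0, abs=1e-6)
        assert pitch == pytest.approx(0.0, abs=1e-6)

    def test_small_angle_perturbations_recover_sd(self, rng):
        """Monte-Carlo: RMSD converges to the per-axis perturbation SD."""
        n = 10_000
        t = np.arange(n) / FS
        yaw0, pitch0, roll0 = 0.2, -0.1, 0.3
        q_ref = constant_orientation(t, quat.from_euler_zyx(yaw0, pitch0, roll0))
        sd = np.deg2rad([0.5, 0.8, 1.5])  # roll, pitch, yaw
        noise = rng.standard_normal((n, 3)) * sd
        q_est = quat.from_euler_zyx(yaw0 + noise[:, 2], pitch0 + noise[:, 1],
                                    roll0 + noise[:, 0])
        q_est = QuaternionSeries(t, quat.enforce_sign_continuity(q_est))
        roll, pitch, yaw = angle_rmsd(q_est, q_ref)
        assert roll == pytest.approx(0.5, rel=0.05)
        assert pitch == pytest.approx(0.8, rel=0.05)
        assert yaw == pytest.approx(1.5, rel=0.05)

    def test_empty_window_rejected(self, default_trial):
        q = default_trial.truth_quat
        with pytest.raises(ValueError):
            angle_rmsd(q, q, trim_s=1e6)
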