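"""Orientation estimation for the lower-trunk unit.

A minimal quaternion extended Kalman filter: the state is the unit quaternion
rotating ULF -> GGF, propagated by gyroscope kinematics and corrected by the
accelerometer-measured gravity direction.  No magnetometer is used, so the
heading (yaw) evolves by gyro integration only and is unobservable; no bias
states are kept — the constant gyroscope bias is instead captured during the
standing-rest prefix of each trial and subtracted up front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import quat
from .core import GRAVITY_MS2, ImuRecording, QuaternionSeries


@dataclass
class OrientationFilterParams:
    """EKF tuning knobs.

    gyro_noise_density : rad/s/√Hz, angular random walk of the gyros.
    accel_meas_noise   : m/s², effective measurement noise of the specific
                         force seen as a gravity observation; it budgets both
                         sensor noise and the (zero-mean over a stride)
                         linear acceleration, so it is deliberately large.
    accel_gate         : m/s², specific-force-norm deviation from g above
                         which the accelerometer update is skipped (the
                         sample is dominated by linear acceleration).
    initial_covariance : initial state variance (quaternion components).
    """

    gyro_noise_density: float = 3.5e-4
    accel_meas_noise: float = 2.0
    accel_gate: float = 6.0
    initial_covariance: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("gyro_noise_density", "accel_meas_noise", "accel_gate",
                     "initial_covariance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def estimate_gyro_bias(rest_gyro: np.ndarray) -> np.ndarray:
    """Constant gyro bias as the mean reading over the standing-rest window."""
    rest_gyro = np.asarray(rest_gyro, dtype=float)
    if rest_gyro.ndim != 2 or rest_gyro.shape[1] != 3:
        raise ValueError("rest_gyro must be (n, 3)")
    return rest_gyro.mean(axis=0)


def initial_attitude_from_rest(rest_specific_force: np.ndarray) -> np.ndarray:
    """Roll/pitch attitude from the rest-period specific force; yaw = 0.

    The mean specific force at rest points opposite to gravity in the sensor
    frame; roll and pitch are chosen so R(q)ᵀ e_z matches it, heading is left
    at zero because it is unobservable without a magnetometer.
    """
    f = np.asarray(rest_specific_force, dtype=float)
    if f.ndim != 2 or f.shape[1] != 3:
        raise ValueError("rest_specific_force must be (n, 3)")
    f_mean = f.mean(axis=0)
    norm = np.linalg.norm(f_mean)
    if abs(norm - GRAVITY_MS2) > 0.05 * GRAVITY_MS2:
        raise ValueError(
            f"rest specific-force norm {norm:.2f} m/s2 deviates more than 5% "
            "from gravity; the unit does not appear to be at rest"
        )
    u = -f_mean / norm  # = R(q)ᵀ e_z = (-sinθ, sinφ cosθ, cosφ cosθ)
    pitch = np.arcsin(np.clip(-u[0], -1.0, 1.0))
    roll = np.arctan2(u[1], u[2])
    return quat.from_euler_zyx(0.0, pitch, roll)


def _xi(q: np.ndarray) -> np.ndarray:
    """4x3 matrix mapping body rotation-vector noise n to d(q ⊗ (0, n/2))."""
    w, x, y, z = q
    return 0.5 * np.array(
        [[-x, -y, -z],
         [w, -z, y],
         [z, w, -x],
         [-y, x, w]]
    )


def _right_mult_matrix(q: np.ndarray) -> np.ndarray:
    """Matrix M with M p = p ⊗ q."""
    w, x, y, z = q
    return np.array(
        [[w, -x, -y, -z],
         [x, w, z, -y],
         [y, -z, w, x],
         [z, y, -x, w]]
    )


def _gravity_direction_jacobian(q: np.ndarray) -> np.ndarray:
    """Jacobian of h(q) = -R(q)ᵀ e_z with respect to (w, x, y, z)."""
    w, x, y, z = q
    return np.array(
        [[2 * y, -2 * z, 2 * w, -2 * x],
         [-2 * x, -2 * w, -2 * z, -2 * y],
         [0.0, 4 * x, 4 * y, 0.0]]
    )


def ekf_orientation(imu: ImuRecording, q0: np.ndarray,
                    params: OrientationFilterParams | None = None,
                    accel_updates: bool = True) -> QuaternionSeries:
    """Run the quaternion EKF over a recording.

    Parameters
    ----------
    imu : recording with bias-corrected gyro (rad/s) and specific force.
    q0 : initial unit quaternion (ULF -> GGF).
    accel_updates : disable to integrate gyro kinematics only (useful for
        drift studies and closed-form comparisons).
    """
    params = params or OrientationFilterParams()
    q = np.asarray(q0, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-6:
        raise ValueError("q0 must be a unit quaternion")
    q = q / np.linalg.norm(q)

    dt = 1.0 / imu.sampling_rate
    sigma_g = params.gyro_noise_density * np.sqrt(imu.sampling_rate)
    r_meas = params.accel_meas_noise**2 * np.eye(3)
    p_cov = params.initial_covariance * np.eye(4)
    eye4 = np.eye(4)

    n = len(imu)
    out = np.empty((n, 4))
    out[0] = q
    gyro = imu.gyro
    force = imu.specific_force
    for k in range(1, n):
        # propagate: q_k = q_{k-1} ⊗ exp(½ ω dt), body-frame rates
        dq = quat.exp_map(gyro[k - 1] * dt)
        f_mat = _right_mult_matrix(dq)
        q = f_mat @ q
        xi = _xi(q)
        p_cov = f_mat @ p_cov @ f_mat.T + (sigma_g * dt) ** 2 * (xi @ xi.T)

        if accel_updates:
            f_k = force[k]
            f_norm = np.linalg.norm(f_k)
            if abs(f_norm - GRAVITY_MS2) <= params.accel_gate and f_norm > 0:
                # predicted specific force at rest: h(q) = -R(q)ᵀ g
                z = f_k
                w, x, y, zz = q
                h = -GRAVITY_MS2 * np.array(
                    [2 * (x * zz - w * y), 2 * (y * zz + w * x),
                     1.0 - 2.0 * (x * x + y * y)]
                )
                h_jac = GRAVITY_MS2 * _gravity_direction_jacobian(q)
                s = h_jac @ p_cov @ h_jac.T + r_meas
                gain = p_cov @ h_jac.T @ np.linalg.solve(s, np.eye(3))
                q = q + gain @ (z - h)
                p_cov = (eye4 - gain @ h_jac) @ p_cov

        q = q / np.linalg.norm(q)
        out[k] = q

    return QuaternionSeries(time=imu.time, q=out)


def constant_orientation(time: np.ndarray, q: np.ndarray) -> QuaternionSeries:
    """Hold a single quaternion for a whole trial (the 'initial rotation')."""
    q = np.asarray(q, dtype=float)
    return QuaternionSeries(time=time, q=np.tile(q / np.linalg.norm(q),
                                                 (len(time), 1)))


def angle_rmsd(q_est: QuaternionSeries, q_ref: QuaternionSeries,
               trim_s: float = 0.0) -> tuple[float, float, float]:
    """RMS deviation of Euler angles (roll, pitch, yaw) in degrees.

    Both series must share a time grid; ``trim_s`` seconds are discarded from
    each end before comparison.  Angle differences are wrapped to
    (-180, 180] so yaw wrap-around does not inflate the statistic.
    """
    if len(q_est) != len(q_ref) or np.any(np.abs(q_est.time - q_ref.time) > 1e-9):
        raise ValueError("series must share a common time grid")
    keep = (q_est.time >= q_est.time[0] + trim_s) & (
        q_est.time <= q_est.time[-1] - trim_s
    )
    if not np.any(keep):
        raise ValueError("no samples retained after trimming")
    e_est = quat.to_euler_zyx(q_est.q[keep], degrees=True)  # (yaw, pitch, roll)
    e_ref = quat.to_euler_zyx(q_ref.q[keep], degrees=True)
    diff = e_est - e_ref
    diff = (diff + 180.0) % 360.0 - 180.0
    rms = np.sqrt(np.mean(diff**2, axis=0))
    return float(rms[2]), float(rms[1]), float(rms[0])  # roll, pitch, yaw
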