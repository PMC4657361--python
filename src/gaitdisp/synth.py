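"""Synthetic treadmill-walking trials with ground truth.

The generator emulates the validation protocol the estimator is meant for:
2-min treadmill trials at 3-7 km/h preceded by a 5-s standing rest, recorded
by a lower-trunk IMU (100 Hz) with a shank gyroscope for gait segmentation.
Pelvis displacement is built per stride from a small, fixed harmonic recipe
(ML dominated by stride frequency; VT and AP by step frequency, twice the
stride frequency) scaled to published peak-to-trough amplitudes, plus a slow
non-periodic horizontal sway.  Trunk orientation sways periodically within
published angular ranges around a baseline standing tilt.  All kinematics are
analytic in time, so the simulated specific force is exactly consistent with
the ground-truth displacement and orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import quat
from .core import (GRAVITY_GGF, ImuRecording, QuaternionSeries, Trace3D,
                   mlvtap_to_ggf_xyz)

#: study conditions per treadmill speed (km/h): mean stride time (s),
#: stride-time CV (%), displacement peak-to-trough (ML, VT, AP; mm) and
#: angular range of motion (roll, pitch, yaw; deg)
SPEED_CONDITIONS = {
    3: dict(stride_time=1.32, stride_cv=2.26, p2t_mm=(60.0, 16.0, 28.0),
            sway_deg=(9.3, 7.3, 16.0)),
    4: dict(stride_time=1.13, stride_cv=1.68, p2t_mm=(47.0, 26.0, 25.0),
            sway_deg=(9.4, 7.6, 12.9)),
    5: dict(stride_time=1.02, stride_cv=1.36, p2t_mm=(39.0, 35.0, 24.0),
            sway_deg=(10.4, 6.9, 13.9)),
    6: dict(stride_time=0.94, stride_cv=1.26, p2t_mm=(36.0, 44.0, 21.0),
            sway_deg=(11.6, 7.6, 16.1)),
    7: dict(stride_time=0.87, stride_cv=1.47, p2t_mm=(34.0, 52.0, 20.0),
            sway_deg=(13.3, 8.7, 19.5)),
}

# Per-axis harmonic displacement recipes: (harmonic k of the stride cycle,
# relative cosine amplitude, relative sine amplitude).  ML moves once per
# stride; VT and AP twice (once per step) with a small once-per-stride
# left/right asymmetry that makes the two steps distinguishable.
_DISPL_RECIPE = {
    "ml": ((1, 1.0, 0.25), (2, 0.10, 0.05), (3, 0.04, 0.0)),
    "vt": ((2, 1.0, 0.30), (1, 0.08, 0.04), (4, 0.12, 0.0), (6, 0.03, 0.0)),
    "ap": ((2, 1.0, 0.35), (1, 0.12, 0.10), (4, 0.08, 0.0)),
}

# Angular sway: (harmonic k, phase offset rad).  Roll and yaw follow the
# stride cycle, pitch the step cycle; amplitudes come from the configured
# range of motion (peak-to-peak).
_ANGLE_RECIPE = {"roll": (1, 0.4), "pitch": (2, 1.0), "yaw": (1, -2.0)}

# baseline standing posture (deg): slight anterior pelvic tilt
_BASE_ROLL_DEG = 1.0
_BASE_PITCH_DEG = 4.0

# shank ML angular-velocity template amplitudes (rad/s) and relative timings
_SHANK_SWING_AMP = np.deg2rad(300.0)
_SHANK_TOEOFF_AMP = np.deg2rad(80.0)
_SHANK_HS_AMP = np.deg2rad(150.0)


@dataclass
class TrialConfig:
    """Conditions of one simulated trial.  Defaults follow the study design."""

    speed_kmh: int = 5
    duration_s: float = 120.0
    rest_s: float = 5.0
    sampling_rate: float = 100.0
    stride_time_mean: float | None = None   # s; default from SPEED_CONDITIONS
    stride_time_cv: float | None = None     # %; default from SPEED_CONDITIONS
    p2t_mm: tuple[float, float, float] | None = None  # ML, VT, AP targets
    sway_deg: tuple[float, float, float] | None = None  # roll, pitch, yaw ROM
    slow_sway_mm: float = 6.0               # SD of the slow horizontal sway
    slow_sway_corner_hz: float = 0.08
    tilt_drift_deg: float = 0.0             # slow roll drift over the trial
    accel_noise_sd: float = 0.02            # m/s²
    gyro_noise_sd: float = np.deg2rad(0.2)  # rad/s
    gyro_bias: float = np.deg2rad(0.5)      # rad/s, constant random direction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_kmh not in SPEED_CONDITIONS:
            raise ValueError("speed_kmh must be one of 3..7")
        cond = SPEED_CONDITIONS[self.speed_kmh]
        if self.stride_time_mean is None:
            self.stride_time_mean = cond["stride_time"]
        if self.stride_time_cv is None:
            self.stride_time_cv = cond["stride_cv"]
        if self.p2t_mm is None:
            self.p2t_mm = cond["p2t_mm"]
        if self.sway_deg is None:
            self.sway_deg = cond["sway_deg"]
        for name in ("duration_s", "rest_s", "sampling_rate", "stride_time_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("stride_time_cv", "slow_sway_mm", "slow_sway_corner_hz",
                     "accel_noise_sd", "gyro_noise_sd", "gyro_bias",
                     "tilt_drift_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if min(self.p2t_mm) <= 1.0 or max(self.p2t_mm) >= 200.0:
            raise ValueError("displacement targets outside physiological range (mm)")


@dataclass
class SyntheticTrial:
    """One simulated trial with its ground truth."""

    trunk: ImuRecording
    shank: ImuRecording
    truth_quat: QuaternionSeries
    truth_displ: Trace3D
    truth_accel: Trace3D
    heel_strike_times: np.ndarray
    config: TrialConfig


def _draw_stride_durations(cfg: TrialConfig, rng: np.random.Generator) -> np.ndarray:
    mean = cfg.stride_time_mean
    sd = cfg.stride_time_cv / 100.0 * mean
    n = int(np.ceil(cfg.duration_s / max(mean - 3 * sd, 0.3))) + 2
    if sd == 0:
        return np.full(n, mean)
    return stats.truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, size=n,
                               random_state=rng)


def _recipe_arrays(recipe) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = np.array([r[0] for r in recipe], dtype=float)
    c = np.array([r[1] for r in recipe], dtype=float)
    s = np.array([r[2] for r in recipe], dtype=float)
    return k, c, s


def _axis_scale(recipe, target_m: float) -> float:
    """Scale factor so the periodic shape's peak-to-trough equals target."""
    k, c, s = _recipe_arrays(recipe)
    phi = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    shape = np.cos(np.outer(phi, k)) @ c + np.sin(np.outer(phi, k)) @ s
    return target_m / (shape.max() - shape.min())


def generate_trial(config: TrialConfig) -> SyntheticTrial:
    """Simulate one treadmill trial; fully reproducible from ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    dt = 1.0 / fs
    n = int(round((cfg.rest_s + cfg.duration_s) * fs))
    time = np.arange(n) * dt
    t_end = time[-1]

    durations = _draw_stride_durations(cfg, rng)
    hs = cfg.rest_s + np.concatenate([[0.0], np.cumsum(durations)])
    hs = hs[hs <= cfg.rest_s + cfg.duration_s + 1e-9]
    durations = durations[: len(hs)]  # duration of stride starting at hs[i]

    walking = time >= cfg.rest_s - 1e-12
    t_walk = time[walking]
    stride_idx = np.clip(np.searchsorted(hs, t_walk, side="right") - 1, 0,
                         len(hs) - 1)
    T_i = durations[stride_idx]
    tau = t_walk - hs[stride_idx]
    phi = 2.0 * np.pi * tau / T_i          # stride phase in [0, 2π)
    phi_rate = 2.0 * np.pi / T_i

    # --- ground-truth displacement (m) and its analytic second derivative ---
    displ = np.zeros((n, 3))
    accel = np.zeros((n, 3))
    for col, axis in enumerate(("ml", "vt", "ap")):
        k, c, s = _recipe_arrays(_DISPL_RECIPE[axis])
        scale = _axis_scale(_DISPL_RECIPE[axis], cfg.p2t_mm[col] / 1000.0)
        cosk = np.cos(np.outer(phi, k))
        sink = np.sin(np.outer(phi, k))
        displ[walking, col] = scale * (cosk @ c + sink @ s)
        w2 = (np.outer(phi_rate, k)) ** 2
        accel[walking, col] = -scale * ((w2 * cosk) @ c + (w2 * sink) @ s)
        # rest: freeze at the stride-onset value (phase 0)
        displ[~walking, col] = scale * np.sum(c)

    # slow non-periodic horizontal sway (analytic: sum of slow sinusoids)
    if cfg.slow_sway_mm > 0:
        t_rel = np.maximum(time - cfg.rest_s, 0.0)
        n_terms = 4
        amp = cfg.slow_sway_mm / 1000.0 * np.sqrt(2.0 / n_terms)
        for col in (0, 2):  # ML and AP only
            freqs = cfg.slow_sway_corner_hz * (0.3 + 0.7 * rng.random(n_terms))
            phases = rng.uniform(0.0, 2.0 * np.pi, n_terms)
            arg = 2.0 * np.pi * np.outer(t_rel, freqs) + phases
            displ[:, col] += amp * np.sin(arg).sum(axis=1)
            sway_acc = -amp * ((2.0 * np.pi * freqs) ** 2 * np.sin(arg)).sum(axis=1)
            accel[walking, col] += sway_acc[walking]

    truth_displ = Trace3D.from_data(time, displ, "displacement")
    truth_accel = Trace3D.from_data(time, accel, "acceleration")

    # --- ground-truth orientation: baseline tilt + periodic sway (+ drift) ---
    angles = {}
    rates = {}
    rom = dict(zip(("roll", "pitch", "yaw"), np.deg2rad(np.asarray(cfg.sway_deg))))
    base = {"roll": np.deg2rad(_BASE_ROLL_DEG), "pitch": np.deg2rad(_BASE_PITCH_DEG),
            "yaw": 0.0}
    for name, (k_a, ph) in _ANGLE_RECIPE.items():
        amp = rom[name] / 2.0
        a = np.full(n, base[name] + amp * np.cos(ph))
        r = np.zeros(n)
        a[walking] = base[name] + amp * np.cos(k_a * phi + ph)
        r[walking] = -amp * k_a * np.sin(k_a * phi + ph) * phi_rate
        angles[name] = a
        rates[name] = r
    if cfg.tilt_drift_deg:
        drift_rate = np.deg2rad(cfg.tilt_drift_deg) / cfg.duration_s
        ramp = np.maximum(time - cfg.rest_s, 0.0)
        angles["roll"] = angles["roll"] + drift_rate * ramp
        rates["roll"] = rates["roll"] + drift_rate * (time >= cfg.rest_s)

    q_truth = quat.enforce_sign_continuity(
        quat.from_euler_zyx(angles["yaw"], angles["pitch"], angles["roll"])
    )
    truth_quat = QuaternionSeries(time=time, q=q_truth)

    # body angular velocity from intrinsic Z-Y-X Euler rates
    cr, sr = np.cos(angles["roll"]), np.sin(angles["roll"])
    cp, sp = np.cos(angles["pitch"]), np.sin(angles["pitch"])
    omega = np.stack(
        [
            rates["roll"] - rates["yaw"] * sp,
            rates["pitch"] * cr + rates["yaw"] * cp * sr,
            -rates["pitch"] * sr + rates["yaw"] * cp * cr,
        ],
        axis=1,
    )

    # --- trunk IMU streams ---
    a_ggf = mlvtap_to_ggf_xyz(accel)
    f_ulf = quat.rotate_inverse(q_truth, a_ggf - GRAVITY_GGF)
    bias_dir = rng.standard_normal(3)
    bias_dir /= np.linalg.norm(bias_dir)
    gyro_bias = cfg.gyro_bias * bias_dir
    trunk = ImuRecording(
        time=time,
        gyro=omega + gyro_bias + cfg.gyro_noise_sd * rng.standard_normal((n, 3)),
        specific_force=f_ulf + cfg.accel_noise_sd * rng.standard_normal((n, 3)),
        sampling_rate=fs,
        site="lower_trunk",
    )

    # --- shank gyroscope: template ML angular velocity ---
    shank_ml = np.zeros(n)
    for i in range(len(hs) - 1):
        t0, T = hs[i], durations[i]
        for center, width, amp in (
            (t0 + 0.8 * T, 0.06 * T, _SHANK_SWING_AMP),
            (t0 + 0.6 * T, 0.05 * T, -_SHANK_TOEOFF_AMP),
        ):
            lo = np.searchsorted(time, center - 5 * width)
            hi = np.searchsorted(time, center + 5 * width)
            shank_ml[lo:hi] += amp * np.exp(-(((time[lo:hi] - center) / width) ** 2))
    hs_width = 0.025 * cfg.stride_time_mean
    for t_hs in hs:
        lo = np.searchsorted(time, t_hs - 5 * hs_width)
        hi = np.searchsorted(time, t_hs + 5 * hs_width)
        shank_ml[lo:hi] -= _SHANK_HS_AMP * np.exp(
            -(((time[lo:hi] - t_hs) / hs_width) ** 2)
        )
    shank_gyro = cfg.gyro_noise_sd * rng.standard_normal((n, 3))
    shank_gyro[:, 1] += shank_ml
    shank_bias_dir = rng.standard_normal(3)
    shank_bias_dir /= np.linalg.norm(shank_bias_dir)
    shank_gyro += cfg.gyro_bias * shank_bias_dir
    shank_f = np.tile(-GRAVITY_GGF, (n, 1))  # roughly level, unused downstream
    shank = ImuRecording(
        time=time,
        gyro=shank_gyro,
        specific_force=shank_f + cfg.accel_noise_sd * rng.standard_normal((n, 3)),
        sampling_rate=fs,
        site="shank",
    )

    return SyntheticTrial(
        trunk=trunk, shank=shank, truth_quat=truth_quat, truth_displ=truth_displ,
        truth_accel=truth_accel, heel_strike_times=hs, config=cfg,
    )
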