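"""Reference frames, domain containers, gravity compensation and filtering.

Axis conventions
----------------
The global gravity-aligned frame (GGF) has X antero-posterior (positive
forward), Y medio-lateral (positive right) and Z vertical, aligned with
gravity and positive *downwards*; hence gravity is ``(0, 0, +9.81)`` m/s².
The sensor unit local frame (ULF) uses the same axis meanings attached to the
unit.  3-component kinematic traces are always reported in the fixed axis
order ML, VT, AP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from . import quat

GRAVITY_MS2 = 9.81
#: gravity vector in the GGF (Z positive down)
GRAVITY_GGF = np.array([0.0, 0.0, GRAVITY_MS2])

#: index of each anatomical axis in GGF (X, Y, Z) coordinates
GGF_AXIS = {"ap": 0, "ml": 1, "vt": 2}
AXES = ("ml", "vt", "ap")

_GRID_TOL_S = 1e-9


def _check_uniform_time(time: np.ndarray, sampling_rate: float) -> None:
    dt = np.diff(time)
    if time.ndim != 1 or len(time) < 2:
        raise ValueError("time grid needs at least two samples")
    if np.any(np.abs(dt - 1.0 / sampling_rate) > _GRID_TOL_S):
        raise ValueError("time grid is not uniform at the declared sampling rate")


@dataclass
class ImuRecording:
    """Uniformly sampled tri-axial gyroscope + specific-force streams.

    gyro is in rad/s and specific_force in m/s², both resolved in the ULF of
    the unit at ``site`` (``lower_trunk`` or ``shank``).
    """

    time: np.ndarray
    gyro: np.ndarray
    specific_force: np.ndarray
    sampling_rate: float
    site: str = "lower_trunk"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.specific_force = np.asarray(self.specific_force, dtype=float)
        _check_uniform_time(self.time, self.sampling_rate)
        for name, arr in (("gyro", self.gyro), ("specific_force", self.specific_force)):
            if arr.shape != (len(self.time), 3):
                raise ValueError(f"{name} must have shape (n_samples, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite samples")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class QuaternionSeries:
    """Per-sample unit quaternions rotating ULF -> GGF (scalar-first Hamilton)."""

    time: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.time), 4):
            raise ValueError("q must have shape (n_samples, 4)")
        norms = np.linalg.norm(self.q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must be unit norm")
        self.q = quat.enforce_sign_continuity(self.q / norms[:, None])

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class Trace3D:
    """A 3-component kinematic trace on ML/VT/AP axes.

    ``quantity`` declares the physical quantity carried (``acceleration``,
    ``velocity`` or ``displacement``), in m/s², m/s or m.
    """

    time: np.ndarray
    ml: np.ndarray
    vt: np.ndarray
    ap: np.ndarray
    quantity: str = "acceleration"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        self.vt = np.asarray(self.vt, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        n = len(self.time)
        if not (len(self.ml) == len(self.vt) == len(self.ap) == n):
            raise ValueError("axis arrays must match the time grid length")
        for arr in (self.ml, self.vt, self.ap):
            if not np.all(np.isfinite(arr)):
                raise ValueError("trace contains non-finite samples")

    @property
    def data(self) -> np.ndarray:
        """(n, 3) array in ML, VT, AP order."""
        return np.stack([self.ml, self.vt, self.ap], axis=1)

    @classmethod
    def from_data(cls, time: np.ndarray, data: np.ndarray, quantity: str) -> "Trace3D":
        data = np.asarray(data, dtype=float)
        return cls(time=time, ml=data[:, 0], vt=data[:, 1], ap=data[:, 2],
                   quantity=quantity)

    def slice(self, sl: slice) -> "Trace3D":
        return replace(self, time=self.time[sl], ml=self.ml[sl], vt=self.vt[sl],
                       ap=self.ap[sl])

    def __len__(self) -> int:
        return len(self.time)


def ggf_xyz_to_mlvtap(vec_xyz: np.ndarray) -> np.ndarray:
    """Reorder (n, 3) GGF X/Y/Z components to ML/VT/AP columns."""
    vec_xyz = np.asarray(vec_xyz, dtype=float)
    return vec_xyz[..., [GGF_AXIS["ml"], GGF_AXIS["vt"], GGF_AXIS["ap"]]]


def mlvtap_to_ggf_xyz(vec: np.ndarray) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    out = np.empty_like(vec)
    out[..., GGF_AXIS["ml"]] = vec[..., 0]
    out[..., GGF_AXIS["vt"]] = vec[..., 1]
    out[..., GGF_AXIS["ap"]] = vec[..., 2]
    return out


def strapdown_linear_acceleration(imu: ImuRecording,
                                  quats: QuaternionSeries) -> Trace3D:
    """Gravity-compensated linear acceleration in the GGF.

    Rotates the measured specific force into the global frame with the
    per-sample quaternion and adds gravity: ``a = R(q) f + g``.  At rest
    (f = -R(q)ᵀ g) the result is zero.
    """
    if len(imu) != len(quats) or np.any(np.abs(imu.time - quats.time) > _GRID_TOL_S):
        raise ValueError("IMU and quaternion series must share the same time grid")
    a_ggf = quat.rotate(quats.q, imu.specific_force) + GRAVITY_GGF
    return Trace3D.from_data(imu.time, ggf_xyz_to_mlvtap(a_ggf), "acceleration")


def zero_phase_filter(x: np.ndarray, fs: float, cutoff: float, kind: str = "lowpass",
                      order: int = 2) -> np.ndarray:
    """Forward-backward Butterworth filtering (zero phase lag).

    The effective magnitude response is the square of a single-pass
    Butterworth of the given order; at the cutoff frequency the two-pass
    gain is 0.5.  Applies along the first axis; odd reflective padding.
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= fs / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if kind not in ("lowpass", "highpass"):
        raise ValueError("kind must be 'lowpass' or 'highpass'")
    sos = signal.butter(order, cutoff, btype=kind, fs=fs, output="sos")
    padlen = min(x.shape[0] - 1, 3 * (2 * order + 1) * 10)
    return signal.sosfiltfilt(sos, x, axis=0, padtype="odd", padlen=padlen)
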