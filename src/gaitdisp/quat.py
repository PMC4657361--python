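"""Unit-quaternion algebra, scalar-first Hamilton convention.

Quaternions are arrays ``(..., 4)`` ordered ``(w, x, y, z)`` and represent the
rotation taking vectors from the sensor (unit local) frame to the global
gravity-aligned frame: ``v_global = R(q) v_body``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q (broadcasting over leading axes)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = np.moveaxis(p, -1, 0)
    qw, qx, qy, qz = np.moveaxis(q, -1, 0)
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply R(q) to vectors v, i.e. body -> global."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # v' = v + 2 w (u × v) + 2 u × (u × v)
    uv = np.cross(u, v)
    return v + 2.0 * w * uv + 2.0 * np.cross(u, uv)


def rotate_inverse(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply R(q)ᵀ to vectors v, i.e. global -> body."""
    return rotate(conjugate(q), v)


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def exp_map(phi: np.ndarray) -> np.ndarray:
    """Quaternion exponential of rotation vectors phi (..., 3): exp(½ phi)."""
    phi = np.asarray(phi, dtype=float)
    angle = np.linalg.norm(phi, axis=-1, keepdims=True)
    half = 0.5 * angle
    # sinc form is safe at angle -> 0
    k = 0.5 * np.sinc(half / np.pi)
    return np.concatenate([np.cos(half), k * phi], axis=-1)


def to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of q (body -> global)."""
    return Rotation.from_quat(np.asarray(q, dtype=float), scalar_first=True).as_matrix()


def from_matrix(m: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(m).as_quat(scalar_first=True)


def from_euler_zyx(yaw: np.ndarray, pitch: np.ndarray, roll: np.ndarray,
                   degrees: bool = False) -> np.ndarray:
    """Intrinsic Z-Y-X (yaw, pitch, roll) Euler angles to quaternion."""
    ang = np.stack(np.broadcast_arrays(yaw, pitch, roll), axis=-1)
    return Rotation.from_euler("ZYX", ang, degrees=degrees).as_quat(scalar_first=True)


def to_euler_zyx(q: np.ndarray, degrees: bool = False) -> np.ndarray:
    """Quaternion to intrinsic Z-Y-X Euler angles (..., 3) = (yaw, pitch, roll)."""
    return Rotation.from_quat(np.asarray(q, dtype=float), scalar_first=True).as_euler(
        "ZYX", degrees=degrees
    )


def enforce_sign_continuity(q: np.ndarray) -> np.ndarray:
    """Flip signs so consecutive quaternions have non-negative dot product."""
    q = np.array(q, dtype=float, copy=True)
    dots = np.sum(q[1:] * q[:-1], axis=-1)
    flips = np.cumprod(np.where(dots < 0.0, -1.0, 1.0))
    q[1:] *= flips[:, None]
    return q
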