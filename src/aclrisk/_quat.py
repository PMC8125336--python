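"""Minimal unit-quaternion kernel shared by the orientation estimator and the
signal generator.

Convention: scalar-first ``[w, x, y, z]``; a quaternion ``q`` maps sensor-frame
vectors into the world frame, ``v_world = q * v * q^-1``. Euler angles are
intrinsic x-y-z, degrees.
"""

from __future__ import annotations

import numpy as np


def mul(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector ``v`` by quaternion ``q`` (sensor -> world)."""
    qv = np.array([0.0, *v])
    return mul(mul(q, qv), conj(q))[1:]


def to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    half = 0.5 * angle_rad
    return np.array([np.cos(half), *(np.sin(half) * axis / n)])


def exp_map(w: np.ndarray) -> np.ndarray:
    """Quaternion exponential of a rotation vector (rad)."""
    angle = np.linalg.norm(w)
    if angle < 1e-12:
        return normalize(np.array([1.0, *(0.5 * w)]))
    return from_axis_angle(w, angle)


def log_map(q: np.ndarray) -> np.ndarray:
    """Rotation vector (rad) of a unit quaternion, shortest arc."""
    q = normalize(q)
    if q[0] < 0:
        q = -q
    vec = q[1:]
    s = np.linalg.norm(vec)
    if s < 1e-12:
        return 2.0 * vec
    return 2.0 * np.arctan2(s, q[0]) * vec / s


def from_two_vectors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit direction ``a`` onto unit direction ``b``."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:  # antipodal: pick any perpendicular axis
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        return from_axis_angle(axis, np.pi)
    axis = np.cross(a, b)
    q = np.array([1.0 + c, *axis])
    return normalize(q)


def euler_xyz_deg(q: np.ndarray) -> np.ndarray:
    """Intrinsic x-y-z angles (deg) of the rotation, R = Rx Ry Rz."""
    m = to_matrix(q)
    sy = np.clip(m[0, 2], -1.0, 1.0)
    theta_y = np.arcsin(sy)
    theta_x = np.arctan2(-m[1, 2], m[2, 2])
    theta_z = np.arctan2(-m[0, 1], m[0, 0])
    return np.degrees([theta_x, theta_y, theta_z])
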