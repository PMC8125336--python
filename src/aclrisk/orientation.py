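"""Shank-IMU orientation: static re-alignment, Mahony filtering, sway projection.

The processing chain mirrors a standard single-IMU posturography workflow:

1. A static upright trial gives the fixed rotation that re-aligns the sensor
   axes with the absolute (gravity-aligned) frame.
2. A Mahony complementary filter fuses the re-aligned gyroscope and
   accelerometer (6-axis; the magnetometer is deliberately unused, so heading
   is pinned to zero at calibration) into a unit-quaternion orientation
   series.
3. The sensor's longitudinal axis S is intersected with the horizontal plane
   1 cm below the sensor origin; the trace of that intersection is the sway
   path from which the stability features are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _quat

GRAVITY = 9.81  # m/s^2, matches the accelerometer convention a_static = (0, 0, +g)


@dataclass
class IMUTrial:
    """Raw timestamped samples of one movement repetition.

    ``accel`` in m/s^2 (specific force, +g on the local z axis at upright
    rest), ``gyro`` in deg/s, optional ``mag`` in uT.
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        n = len(self.time)
        if n < 2:
            raise ValueError("a trial needs at least 2 samples")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel/gyro must be (n, 3) arrays matching time")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.ptp(dt) > 0.1 * np.median(dt):
            raise ValueError("time-step jitter exceeds 10% of nominal")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_csv(self, path: str | Path) -> None:
        cols = {"time_s": self.time}
        for i, ax in enumerate("xyz"):
            cols[f"a{ax}"] = self.accel[:, i]
        for i, ax in enumerate("xyz"):
            cols[f"g{ax}"] = self.gyro[:, i]
        if self.mag is not None:
            for i, ax in enumerate("xyz"):
                cols[f"m{ax}"] = self.mag[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "IMUTrial":
        df = pd.read_csv(path)
        mag = None
        if {"mx", "my", "mz"} <= set(df.columns):
            mag = df[["mx", "my", "mz"]].to_numpy()
        return cls(
            time=df["time_s"].to_numpy(),
            accel=df[["ax", "ay", "az"]].to_numpy(),
            gyro=df[["gx", "gy", "gz"]].to_numpy(),
            mag=mag,
            meta=meta,
        )


@dataclass
class RotationCorrection:
    """Proper rotation mapping the upright sensor frame to the absolute frame."""

    rotation: np.ndarray  # 3x3

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        self.rotation = R

    @classmethod
    def identity(cls) -> "RotationCorrection":
        return cls(np.eye(3))

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.rotation.T


@dataclass
class OrientationSeries:
    """Absolute-frame orientation of the (re-aligned) sensor over time."""

    time: np.ndarray
    quat: np.ndarray      # (n, 4) scalar-first unit quaternions
    s_axis: np.ndarray    # (n, 3) unit vectors: sensor longitudinal axis, world frame
    theta: np.ndarray     # (n, 3) intrinsic x-y-z angles, degrees

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "qw": self.quat[:, 0], "qx": self.quat[:, 1],
                "qy": self.quat[:, 2], "qz": self.quat[:, 3],
                "sx": self.s_axis[:, 0], "sy": self.s_axis[:, 1],
                "sz": self.s_axis[:, 2],
                "theta_x_deg": self.theta[:, 0],
                "theta_y_deg": self.theta[:, 1],
                "theta_z_deg": self.theta[:, 2],
            }
        ).to_csv(path, index=False)


@dataclass
class SwayPath:
    """2-D trace (cm) of the S-axis intersection with the plane below the sensor.

    Axes: x = medio-lateral (ML), y = antero-posterior (AP).
    """

    time: np.ndarray
    xy: np.ndarray  # (n, 2), cm

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "x_ml_cm": self.xy[:, 0], "y_ap_cm": self.xy[:, 1]}
        ).to_csv(path, index=False)


@dataclass
class MahonyGains:
    """Complementary-filter gains. Kp pulls toward the accelerometer vertical,
    Ki trims gyro bias. ``accel_gate_g`` disables the accelerometer correction
    whenever the measured specific-force magnitude deviates from 1 g by more
    than this fraction — standard practice for impact-heavy recordings, where
    the landing burst otherwise drags the tilt estimate."""

    kp: float = 1.0
    ki: float = 0.3
    accel_gate_g: float = 0.3

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0:
            raise ValueError("gains must be nonnegative")


STILLNESS_GYRO_LIMIT = 5.0  # deg/s, mean |gyro| above this is not a static trial


def estimate_static_alignment(static: IMUTrial) -> RotationCorrection:
    """Re-alignment rotation from a static upright calibration trial.

    The rotation maps the time-averaged accelerometer vector onto
    ``(0, 0, +g)`` through the minimal (heading-free) rotation, so the
    rotation about gravity is pinned to zero.
    """
    if static.duration < 1.0:
        raise ValueError("static calibration must last at least 1 s")
    gyro_mag = np.linalg.norm(static.gyro, axis=1).mean()
    if gyro_mag >= STILLNESS_GYRO_LIMIT:
        raise ValueError(
            f"movement detected during static trial (mean |gyro| = "
            f"{gyro_mag:.1f} deg/s >= {STILLNESS_GYRO_LIMIT})"
        )
    mean_accel = static.accel.mean(axis=0)
    if np.linalg.norm(mean_accel) < 1e-6:
        raise ValueError("static accelerometer mean is zero; cannot align")
    q = _quat.from_two_vectors(mean_accel, [0.0, 0.0, 1.0])
    return RotationCorrection(_quat.to_matrix(q))


def mahony_orientation(
    trial: IMUTrial,
    correction: RotationCorrection | None = None,
    gains: MahonyGains | None = None,
) -> OrientationSeries:
    """Mahony 6-axis orientation estimate of a (re-aligned) trial.

    The first sample is initialised from the accelerometer tilt; afterwards
    the gyroscope is integrated on the quaternion manifold with a
    proportional-integral correction toward the accelerometer vertical
    (gated, see :class:`MahonyGains`). The magnetometer is ignored.
    """
    gains = gains or MahonyGains()
    correction = correction or RotationCorrection.identity()
    if not (np.isfinite(trial.accel).all() and np.isfinite(trial.gyro).all()):
        raise ValueError("non-finite samples in trial")

    accel = correction.apply(trial.accel)
    gyro_rad = np.radians(correction.apply(trial.gyro))
    n = len(trial.time)
    dt = np.diff(trial.time)

    # initial tilt from the accelerometer (identity if it is degenerate)
    a0 = accel[0]
    if np.linalg.norm(a0) > 1e-6:
        # q maps sensor frame -> world: it must take the measured gravity
        # direction onto the world vertical
        q = _quat.from_two_vectors(a0, [0.0, 0.0, 1.0])
    else:
        q = np.array([1.0, 0.0, 0.0, 0.0])

    quats = np.empty((n, 4))
    quats[0] = q
    integral = np.zeros(3)
    for k in range(n - 1):
        # predicted world-vertical expressed in the sensor frame
        w, x, y, z = q
        v_pred = np.array(
            [2 * (x * z - w * y), 2 * (w * x + y * z), w * w - x * x - y * y + z * z]
        )
        a = accel[k]
        a_norm = np.linalg.norm(a)
        omega = gyro_rad[k].copy()
        if abs(a_norm - GRAVITY) < gains.accel_gate_g * GRAVITY:
            err = np.cross(a / a_norm, v_pred)
            integral += gains.ki * err * dt[k]
            omega += gains.kp * err + integral
        q = _quat.mul(q, _quat.exp_map(omega * dt[k]))
        q = _quat.normalize(q)
        quats[k + 1] = q

    s_axis = np.empty((n, 3))
    theta = np.empty((n, 3))
    for k in range(n):
        R = _quat.to_matrix(quats[k])
        s_axis[k] = R[:, 2]  # sensor longitudinal axis in the world frame
        theta[k] = _quat.euler_xyz_deg(quats[k])
    return OrientationSeries(time=trial.time.copy(), quat=quats, s_axis=s_axis, theta=theta)


def project_vertical_axis(orient: OrientationSeries, depth_cm: float = 1.0) -> SwayPath:
    """Sway path: intersection of the S-axis line with the plane ``z = -depth``.

    ``xy_i = -depth * (S_x / S_z, S_y / S_z)`` in cm. The plane is fixed in
    the world frame; for small tilts this reduces to ``depth * tan(tilt)``
    proportionality.
    """
    sz = orient.s_axis[:, 2]
    bad = np.where(sz <= 0.1)[0]
    if bad.size:
        raise ValueError(
            f"sensor axis near-horizontal at sample {bad[0]} "
            f"(S_z = {sz[bad[0]]:.3f} <= 0.1); projection undefined"
        )
    xy = -depth_cm * orient.s_axis[:, :2] / sz[:, None]
    return SwayPath(time=orient.time.copy(), xy=xy)
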