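"""The 13 per-athlete features: sway, load absorption, mobility and timing.

Leg stability is quantified on the sway path with four classical
posturographic measures (Prieto-style): total path length ``PL``, its
antero-posterior and medio-lateral components ``PL_AP``/``PL_ML``, and the
area ``EA`` of the bivariate confidence ellipse covering 99% of the points.
Load absorption (jump task only) is the RMS of the gravity-free shank
acceleration, vertical (``RMS_z``) and horizontal (``RMS_xy``). Every
stability/load measure is computed on the task's critical interval —
``[contact, contact + Ts]`` for the jump, the descent for the squat — and
divided by that interval's duration; leg mobility is the peak knee-flexion
angle ``theta_ymax``. Features are finally averaged over the five
repetitions of each task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import events as _events
from . import orientation as _orientation
from .orientation import GRAVITY, IMUTrial, MahonyGains, RotationCorrection, SwayPath

#: canonical feature order of the 13-entry vector
FEATURE_NAMES = [
    "mCMJ_Ts",
    "mCMJ_PL",
    "mCMJ_PL_AP",
    "mCMJ_PL_ML",
    "mCMJ_EA",
    "mCMJ_RMS_z",
    "mCMJ_RMS_xy",
    "SLS_T_DP",
    "SLS_PL",
    "SLS_PL_AP",
    "SLS_PL_ML",
    "SLS_EA",
    "SLS_theta_ymax",
]


@dataclass
class StabilityParams:
    """Sway-path measures; cm and cm^2, per-second after normalization."""

    PL: float
    PL_AP: float
    PL_ML: float
    EA: float

    def __post_init__(self) -> None:
        if self.EA < 0:
            raise ValueError("EA must be nonnegative")


@dataclass
class LoadAbsorption:
    RMS_z: float
    RMS_xy: float


def _window_slice(path: SwayPath, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return path.xy
    lo, hi = window
    mask = (path.time >= lo) & (path.time <= hi)
    return path.xy[mask]


def path_lengths(
    path: SwayPath, window: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """``(PL, PL_AP, PL_ML)`` summed over consecutive in-window samples.

    ``PL`` is the Euclidean arc length, ``PL_ML``/``PL_AP`` the total
    variation of the x (medio-lateral) and y (antero-posterior) coordinates.
    """
    xy = _window_slice(path, window)
    if len(xy) < 2:
        raise ValueError("need at least 2 samples in the window")
    d = np.diff(xy, axis=0)
    pl = float(np.hypot(d[:, 0], d[:, 1]).sum())
    pl_ml = float(np.abs(d[:, 0]).sum())
    pl_ap = float(np.abs(d[:, 1]).sum())
    return pl, pl_ap, pl_ml


def ellipse_params(
    xy: np.ndarray, level: float = 0.99
) -> tuple[np.ndarray, np.ndarray, float]:
    """Centre, sample covariance and squared Mahalanobis radius of the
    ``level`` confidence ellipse (``r2 = 2 F_level(2, n-2)``).

    The ellipse is ``(p - c)^T S^-1 (p - c) <= r2`` and its area is
    ``pi * r2 * sqrt(det S)``.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n < 3:
        raise ValueError("need at least 3 points for an ellipse")
    centre = xy.mean(axis=0)
    cov = np.cov(xy.T, ddof=1)
    r2 = 2.0 * stats.f.ppf(level, 2, n - 2)
    return centre, cov, r2


def ellipse_area(
    path: SwayPath | np.ndarray,
    window: tuple[float, float] | None = None,
    level: float = 0.99,
) -> float:
    """Area of the bivariate confidence ellipse covering ``level`` of the points.

    ``EA = 2 pi F_level(2, n-2) sqrt(s_x^2 s_y^2 - s_xy^2)`` — the
    F-quantile form of the posturographic ellipse area. A degenerate
    (collinear) cloud yields 0 with a warning.
    """
    xy = path if isinstance(path, np.ndarray) else _window_slice(path, window)
    if len(xy) < 3:
        raise ValueError("need at least 3 points for an ellipse")
    _, cov, r2 = ellipse_params(xy, level)
    det = float(np.linalg.det(cov))
    if det <= 0:
        warnings.warn("degenerate (collinear) sway cloud; EA set to 0")
        return 0.0
    return float(np.pi * r2 * np.sqrt(det))


def rms_load(
    trial: IMUTrial,
    correction: RotationCorrection | None,
    t_contact: float,
    ts: float,
) -> LoadAbsorption:
    """Time-normalized landing-acceleration RMS on ``[contact, contact + Ts]``.

    The accelerometer is rotated to the absolute frame with the static
    correction and gravity is removed from the vertical channel before the
    RMS; both values are divided by ``Ts``.
    """
    if ts <= 0:
        raise ValueError("Ts must be positive")
    correction = correction or RotationCorrection.identity()
    mask = (trial.time >= t_contact) & (trial.time <= t_contact + ts)
    if not mask.any():
        raise ValueError("empty landing window")
    acc = correction.apply(trial.accel[mask])
    acc = acc - np.array([0.0, 0.0, GRAVITY])
    rms_z = float(np.sqrt(np.mean(acc[:, 2] ** 2)))
    rms_xy = float(np.sqrt(np.mean(acc[:, 0] ** 2 + acc[:, 1] ** 2)))
    return LoadAbsorption(RMS_z=rms_z / ts, RMS_xy=rms_xy / ts)


def normalize_stability(params: StabilityParams, duration: float) -> StabilityParams:
    """Divide every sway measure by the window duration (s)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return replace(
        params,
        PL=params.PL / duration,
        PL_AP=params.PL_AP / duration,
        PL_ML=params.PL_ML / duration,
        EA=params.EA / duration,
    )


@dataclass
class FeatureVector:
    """The 13 features of one athlete, averaged over five repetitions per task."""

    athlete_id: str | int
    values: np.ndarray  # length 13, FEATURE_NAMES order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features")
        if not np.isfinite(self.values).all():
            raise ValueError("features must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


MCMJ_KEYS = FEATURE_NAMES[:7]
SLS_KEYS = FEATURE_NAMES[7:]


def build_feature_vector(
    mcmj_reps: Sequence[Mapping[str, float]],
    sls_reps: Sequence[Mapping[str, float]],
    athlete_id: str | int = "athlete",
    n_required: int = 5,
    allow_fewer: bool = False,
) -> FeatureVector:
    """Average per-repetition feature mappings into the fixed 13-entry vector."""
    for name, reps in (("mCMJ", mcmj_reps), ("SLS", sls_reps)):
        if len(reps) == 0:
            raise ValueError(f"no {name} repetitions")
        if len(reps) != n_required:
            if not allow_fewer:
                raise ValueError(
                    f"{name}: expected {n_required} repetitions, got {len(reps)} "
                    "(pass allow_fewer=True to accept)"
                )
            warnings.warn(f"{name}: averaging over {len(reps)} < {n_required} reps")
    values = [np.mean([rep[k] for rep in mcmj_reps]) for k in MCMJ_KEYS]
    values += [np.mean([rep[k] for rep in sls_reps]) for k in SLS_KEYS]
    return FeatureVector(athlete_id, np.array(values))


# ---------------------------------------------------------------------------
# per-repetition extraction (raw signals -> feature mapping)

def extract_jump_features(
    trial: IMUTrial,
    led: _events.LEDSeries,
    correction: RotationCorrection | None = None,
    gains: MahonyGains | None = None,
    depth_cm: float = 1.0,
    lowpass_hz: float = 10.0,
    ellipse_level: float = 0.99,
) -> dict[str, float]:
    """mCMJ repetition: contact + Ts events, sway over the landing window,
    load-absorption RMS; all stability/load values normalized by Ts."""
    orient = _orientation.mahony_orientation(trial, correction, gains)
    t_contact = detect = _events.detect_contact(led)
    ts = _events.stabilization_time(trial, detect, lowpass_hz)
    path = _orientation.project_vertical_axis(orient, depth_cm)
    window = (t_contact, t_contact + ts)
    pl, pl_ap, pl_ml = path_lengths(path, window)
    ea = ellipse_area(path, window, ellipse_level)
    stab = normalize_stability(StabilityParams(pl, pl_ap, pl_ml, ea), ts)
    load = rms_load(trial, correction, t_contact, ts)
    return {
        "mCMJ_Ts": ts,
        "mCMJ_PL": stab.PL,
        "mCMJ_PL_AP": stab.PL_AP,
        "mCMJ_PL_ML": stab.PL_ML,
        "mCMJ_EA": stab.EA,
        "mCMJ_RMS_z": load.RMS_z,
        "mCMJ_RMS_xy": load.RMS_xy,
    }


def extract_squat_features(
    trial: IMUTrial,
    static_trial: IMUTrial,
    correction: RotationCorrection | None = None,
    gains: MahonyGains | None = None,
    depth_cm: float = 1.0,
    sd_factor: float = 5.0,
    sd_window_s: float = 0.5,
    ellipse_level: float = 0.99,
) -> dict[str, float]:
    """SLS repetition: descent window events, sway over the descent, peak
    knee-flexion angle; stability values normalized by T_DP."""
    orient = _orientation.mahony_orientation(trial, correction, gains)
    static_orient = _orientation.mahony_orientation(static_trial, correction, gains)
    t_start, t_end, theta_ymax, t_dp = _events.sls_window(
        orient, static_orient, sd_factor, sd_window_s
    )
    path = _orientation.project_vertical_axis(orient, depth_cm)
    window = (t_start, t_end)
    pl, pl_ap, pl_ml = path_lengths(path, window)
    ea = ellipse_area(path, window, ellipse_level)
    stab = normalize_stability(StabilityParams(pl, pl_ap, pl_ml, ea), t_dp)
    return {
        "SLS_T_DP": t_dp,
        "SLS_PL": stab.PL,
        "SLS_PL_AP": stab.PL_AP,
        "SLS_PL_ML": stab.PL_ML,
        "SLS_EA": stab.EA,
        "SLS_theta_ymax": theta_ymax,
    }


# ---------------------------------------------------------------------------
# feature-table I/O (round-trips with the bench module)

def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    df = pd.DataFrame([v.as_dict() for v in vectors])
    df.insert(0, "athlete_id", [v.athlete_id for v in vectors])
    return df


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df
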