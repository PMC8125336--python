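"""Movement-event detection for the jump and squat tasks.

Three events drive all windowing downstream:

* **Ground contact** (mCMJ) — the first off->on transition of the
  optoelectronic LED status after a search time.
* **Stabilization time** ``Ts`` (mCMJ) — time from contact to the first local
  minimum of the low-pass-filtered magnitude of the shank angular velocity;
  the landing interval ``[contact, contact + Ts]`` is the one most exposed to
  ACL injury and is where the stability and load-absorption features live.
* **Squat descent window** (SLS) — the movement starts when the rolling
  standard deviation of the orientation-angle magnitude exceeds ``k`` times
  the average rolling SD of the static trial, and ends at the maximum of the
  knee-flexion angle ``theta_y``; their difference is the descent duration
  ``T_DP``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .orientation import IMUTrial, OrientationSeries


@dataclass
class LEDSeries:
    """Optoelectronic diode interruption status over time."""

    time: np.ndarray
    on: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.on = np.asarray(self.on, dtype=bool)
        if self.time.shape != self.on.shape:
            raise ValueError("time and on must have equal length")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time, "on": self.on.astype(int)}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LEDSeries":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["on"].to_numpy().astype(bool))


@dataclass
class EventMarks:
    """Detected event times for one repetition (fields unused by a task stay None)."""

    t_contact: float | None = None
    ts: float | None = None
    t_start: float | None = None
    t_end: float | None = None
    t_dp: float | None = None
    theta_ymax: float | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def detect_contact(led: LEDSeries, search_from: float = 0.0) -> float:
    """Time of the first off->on LED transition after ``search_from``."""
    on = led.on
    trans = np.flatnonzero(on[1:] & ~on[:-1]) + 1
    trans = trans[led.time[trans] > search_from]
    if trans.size == 0:
        raise ValueError(f"no off->on LED transition after t = {search_from} s")
    return float(led.time[trans[0]])


def stabilization_time(
    trial: IMUTrial,
    t_contact: float,
    lowpass_hz: float = 10.0,
) -> float:
    """Stabilization time: contact to the first local minimum of |omega|.

    |omega| is the Euclidean norm of the three gyro channels, smoothed with a
    zero-phase 4th-order Butterworth low-pass (``lowpass_hz``, applied
    forward-backward) so that sensor ripple does not create spurious minima.
    A local minimum is a sample strictly below both neighbours; plateaus
    resolve to their earliest sample.
    """
    if trial.time[-1] - t_contact < 0.05:
        raise ValueError("need at least 0.05 s of data after contact")
    omega = np.linalg.norm(trial.gyro, axis=1)
    fs = trial.sample_rate
    if lowpass_hz and lowpass_hz < fs / 2:
        sos = signal.butter(2, lowpass_hz, fs=fs, output="sos")
        omega = signal.sosfiltfilt(sos, omega)

    start = int(np.searchsorted(trial.time, t_contact, side="right"))
    n = len(omega)
    i = max(start, 1)
    while i < n - 1:
        if omega[i] < omega[i - 1]:
            j = i
            while j + 1 < n and omega[j + 1] == omega[i]:
                j += 1
            if j + 1 < n and omega[j + 1] > omega[i]:
                return float(trial.time[i] - t_contact)
            i = j + 1
        else:
            i += 1
    raise ValueError("no local minimum of |omega| found after contact")


def _rolling_sd(x: np.ndarray, win: int) -> np.ndarray:
    """Trailing-window sample SD at every sample (NaN until the window fills)."""
    s = pd.Series(x).rolling(win).std(ddof=1)
    return s.to_numpy()


def sls_window(
    orient: OrientationSeries,
    static_orient: OrientationSeries,
    k: float = 5.0,
    win_s: float = 0.5,
) -> tuple[float, float, float, float]:
    """Detect the squat descent window on an orientation series.

    Returns ``(t_start, t_end, theta_ymax, T_DP)``. The baseline is the mean
    over 50%-overlapping windows of the SD of the angle-vector magnitude on
    the static trial; movement starts when the per-sample trailing-window SD
    of the same quantity exceeds ``k * baseline``, and ends at the maximum of
    ``theta_y`` after the start.
    """
    if static_orient.time[-1] - static_orient.time[0] < 1.0:
        raise ValueError("static orientation series must span at least 1 s")
    fs = orient.sample_rate
    win = max(2, int(round(win_s * fs)))

    mag_static = np.linalg.norm(static_orient.theta, axis=1)
    hop = max(1, win // 2)
    sds = [
        np.std(mag_static[i : i + win], ddof=1)
        for i in range(0, len(mag_static) - win + 1, hop)
    ]
    baseline = float(np.mean(sds))

    mag = np.linalg.norm(orient.theta, axis=1)
    rolling = _rolling_sd(mag, win)
    above = np.flatnonzero(rolling > k * baseline)
    if above.size == 0:
        raise ValueError("movement threshold never crossed")
    # the window that first crossed ends at `above[0]`; motion began inside
    # it, so walk back to where the magnitude actually left its quiet level
    cross = int(above[0])
    pre_lo = max(0, cross - 2 * win)
    pre = mag[pre_lo : max(pre_lo + 2, cross - win)]
    quiet = float(np.median(pre)) if pre.size else float(mag[0])
    start_idx = cross
    while start_idx - 1 > 0 and mag[start_idx - 1] > quiet + 2 * baseline:
        start_idx -= 1
    t_start = float(orient.time[start_idx])

    theta_y = orient.theta[:, 1]
    end_idx = start_idx + int(np.argmax(theta_y[start_idx:]))
    if end_idx >= len(theta_y) - 1:
        raise ValueError("theta_y maximum at the final sample: truncated descent")
    t_end = float(orient.time[end_idx])
    theta_ymax = float(theta_y[end_idx])
    if t_end <= t_start:
        raise ValueError("degenerate descent window (t_end <= t_start)")
    return t_start, t_end, theta_ymax, t_end - t_start
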