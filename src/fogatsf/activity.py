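"""Hip-sensor activity mask: exclusion of sedentary time from all analyses.

Sedentary detection follows the waist-sensor convention: the total hip angular
speed (sum of the absolute values of the three gyro axes, in deg/s) is smoothed
with a centered 20 s moving-average window, and samples whose smoothed value
does not exceed 1 deg/s are sedentary. A participant sitting and bouncing a leg
keeps the hip near zero and is therefore excluded even though a foot sensor
moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .io import ImuRecording

DEFAULT_THRESHOLD_DPS = 1.0
DEFAULT_WINDOW_S = 20.0


@dataclass
class ActivityMask:
    """Per-sample active/sedentary flags aligned to the hip recording's clock."""

    rate_hz: float
    t0_s: float
    flags: np.ndarray  # boolean, True = active

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1 or self.flags.size < 1:
            raise UsageError("flags must be a non-empty 1-d boolean array")

    @property
    def n_samples(self) -> int:
        return self.flags.size

    @property
    def active_seconds(self) -> float:
        return float(self.flags.sum()) / self.rate_hz


def total_angular_speed(rec: ImuRecording) -> np.ndarray:
    """Per-sample total hip angular speed ``|gx| + |gy| + |gz|`` in deg/s."""
    if rec.site != "left_hip":
        raise UsageError(f"total_angular_speed expects the left_hip sensor, got {rec.site!r}")
    return np.abs(rec.gyro).sum(axis=1)


def centered_moving_average(series, window_s: float, rate_hz: float) -> np.ndarray:
    """Centered moving average with windows truncated (shrunk) at the edges.

    Output sample ``k`` is the mean of the input over samples within
    ``±window_s/2`` of ``k``; no padding is invented at the session boundaries.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise UsageError("cannot average an empty series")
    if not window_s > 0:
        raise UsageError("window_s must be positive")
    h = int(round(window_s * rate_hz / 2))
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    k = np.arange(n)
    lo = np.maximum(k - h, 0)
    hi = np.minimum(k + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def compute_activity_mask(
    rec: ImuRecording,
    threshold_dps: float = DEFAULT_THRESHOLD_DPS,
    window_s: float = DEFAULT_WINDOW_S,
    per_axis: bool = False,
) -> ActivityMask:
    """Flag samples as active where smoothed total hip angular speed exceeds the threshold.

    The comparison is strict (``> threshold_dps``): samples at exactly the
    threshold are sedentary. With ``per_axis=True`` each axis' absolute angular
    speed is smoothed separately and a sample is active if any axis exceeds the
    threshold (an alternative reading of the waist-sensor rule; off by default).
    """
    if per_axis:
        smoothed = np.stack(
            [
                centered_moving_average(np.abs(rec.gyro[:, i]), window_s, rec.rate_hz)
                for i in range(3)
            ]
        )
        flags = np.any(smoothed > threshold_dps, axis=0)
    else:
        speed = total_angular_speed(rec)
        flags = centered_moving_average(speed, window_s, rec.rate_hz) > threshold_dps
    return ActivityMask(rate_hz=rec.rate_hz, t0_s=rec.t0_s, flags=flags)
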