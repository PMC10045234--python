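"""Reading, writing and resampling of IMU recordings and interval annotations.

The on-disk dialect is plain CSV. IMU files carry sidecar comment lines
(``#subject=``, ``#site=``, ``#rate_hz=``) followed by a header
``time_s,gyro_x,gyro_y,gyro_z[,accel_x,accel_y,accel_z]``; gyro channels are in
deg/s and accelerometer channels in g. Annotation files have the header
``start_s,end_s,label`` where labels are ``fog`` or ``task:<name>``.

Recordings from 128 Hz hardware are brought to the common 100 Hz analysis rate
with a Hann-windowed sinc interpolator (:func:`resample_sinc`).
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UsageError

SITES = ("left_foot", "right_foot", "left_hip")
FOG_LABEL = "fog"
TASK_PREFIX = "task:"

#: relative clock-jitter tolerance when inferring a uniform rate from timestamps
RATE_JITTER_TOL = 0.01


@dataclass
class ImuRecording:
    """One sensor site's uniformly sampled tri-axial gyro/accel stream.

    Sample ``k`` is taken at session-clock time ``t0_s + k / rate_hz``.
    ``gyro`` is an ``(n, 3)`` array in deg/s; ``accel`` is ``(n, 3)`` in g or
    ``None`` when the file carried no accelerometer columns.
    """

    subject_id: str
    site: str
    rate_hz: float
    t0_s: float
    gyro: np.ndarray
    accel: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise UsageError(f"unknown sensor site {self.site!r}; expected one of {SITES}")
        if not self.rate_hz > 0:
            raise UsageError("rate_hz must be positive")
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.gyro.ndim != 2 or self.gyro.shape[1] != 3 or self.gyro.shape[0] < 1:
            raise UsageError("gyro must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(self.gyro)):
            raise DataError("gyro contains non-finite values")
        if self.accel is not None:
            self.accel = np.asarray(self.accel, dtype=float)
            if self.accel.size == 0:
                self.accel = None
            elif self.accel.shape != self.gyro.shape:
                raise UsageError("accel must be empty or match gyro shape")
            elif not np.all(np.isfinite(self.accel)):
                raise DataError("accel contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.gyro.shape[0]

    @property
    def duration_s(self) -> float:
        """Time span from the first to the last sample."""
        return (self.n_samples - 1) / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.rate_hz


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise FormatError(f"interval end {self.end_s} must exceed start {self.start_s}")
        if self.start_s < 0:
            raise FormatError("interval times must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotationTrack:
    """Labeled time intervals: FOG episodes and/or task spans.

    FOG intervals are normalized on construction: sorted by start and with
    overlapping or abutting episodes unioned into one.
    """

    subject_id: str = ""
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = _normalize_intervals(self.intervals)

    def fog_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == FOG_LABEL]

    def task_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label.startswith(TASK_PREFIX)]

    def task_names(self) -> list[str]:
        return [iv.label[len(TASK_PREFIX):] for iv in self.task_intervals()]

    def total_fog_s(self) -> float:
        return float(sum(iv.duration_s for iv in self.fog_intervals()))

    def __len__(self) -> int:
        return len(self.intervals)


def _normalize_intervals(intervals) -> list[Interval]:
    """Sort by start; union overlapping/abutting FOG intervals, keep tasks as given."""
    fog = sorted((iv for iv in intervals if iv.label == FOG_LABEL), key=lambda iv: iv.start_s)
    other = [iv for iv in intervals if iv.label != FOG_LABEL]
    merged: list[Interval] = []
    for iv in fog:
        if merged and iv.start_s <= merged[-1].end_s:
            if iv.end_s > merged[-1].end_s:
                merged[-1] = Interval(merged[-1].start_s, iv.end_s, FOG_LABEL)
        else:
            merged.append(iv)
    return sorted(merged + other, key=lambda iv: (iv.start_s, iv.label))


# ---------------------------------------------------------------------------
# IMU CSV I/O
# ---------------------------------------------------------------------------

_GYRO_COLS = ["gyro_x", "gyro_y", "gyro_z"]
_ACCEL_COLS = ["accel_x", "accel_y", "accel_z"]


def _read_sidecar(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_imu(path) -> ImuRecording:
    """Read an IMU CSV file into an :class:`ImuRecording`.

    The sampling rate is taken from the ``#rate_hz=`` sidecar line when present
    and is always checked against the median timestamp spacing (1% jitter
    tolerance). Subject and site fall back to a ``<subject>_<site>.csv`` file
    naming convention when no sidecar lines are present.
    """
    path = Path(path)
    meta = _read_sidecar(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if "time_s" not in frame.columns or any(c not in frame.columns for c in _GYRO_COLS):
        raise FormatError(f"{path} must have columns time_s,{','.join(_GYRO_COLS)}")
    if len(frame) < 1:
        raise FormatError(f"{path} contains no samples")

    t = frame["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError(f"{path}: timestamps are not strictly increasing")
        med = float(np.median(dt))
        if np.any(np.abs(dt - med) > RATE_JITTER_TOL * med):
            raise DataError(f"{path}: timestamp spacing deviates more than 1% from uniform")
        rate = 1.0 / med
    else:
        rate = np.nan

    if "rate_hz" in meta:
        rate_meta = float(meta["rate_hz"])
        if np.isfinite(rate) and abs(rate_meta - rate) > RATE_JITTER_TOL * rate_meta:
            raise DataError(
                f"{path}: sidecar rate {rate_meta} Hz disagrees with timestamps ({rate:.6g} Hz)"
            )
        rate = rate_meta
    elif not np.isfinite(rate):
        raise FormatError(f"{path}: single-sample file needs a #rate_hz= sidecar line")

    subject, site = meta.get("subject"), meta.get("site")
    if subject is None or site is None:
        for s in SITES:
            if path.stem.endswith(s):
                site = site or s
                subject = subject or path.stem[: -len(s)].rstrip("_")
                break
    if site is None:
        raise FormatError(f"{path}: no #site= sidecar line and site not inferable from name")

    accel = None
    if all(c in frame.columns for c in _ACCEL_COLS):
        accel = frame[_ACCEL_COLS].to_numpy(dtype=float)
    return ImuRecording(
        subject_id=subject or "unknown",
        site=site,
        rate_hz=rate,
        t0_s=float(t[0]),
        gyro=frame[_GYRO_COLS].to_numpy(dtype=float),
        accel=accel,
    )


def write_imu(rec: ImuRecording, path) -> None:
    """Write an :class:`ImuRecording` to CSV; byte output is deterministic."""
    path = Path(path)
    cols = _GYRO_COLS + (_ACCEL_COLS if rec.accel is not None else [])
    buf = _stdio.StringIO()
    buf.write(f"#subject={rec.subject_id}\n#site={rec.site}\n#rate_hz={rec.rate_hz!r}\n")
    buf.write("time_s," + ",".join(cols) + "\n")
    times = rec.times()
    data = rec.gyro if rec.accel is None else np.hstack([rec.gyro, rec.accel])
    for k in range(rec.n_samples):
        row = ",".join(f"{v:.15g}" for v in data[k])
        buf.write(f"{times[k]:.15g},{row}\n")
    try:
        path.write_text(buf.getvalue(), encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_annotations(path) -> AnnotationTrack:
    """Read an interval CSV (``start_s,end_s,label``) into a normalized track."""
    path = Path(path)
    meta = _read_sidecar(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    for col in ("start_s", "end_s", "label"):
        if col not in frame.columns:
            raise FormatError(f"{path} must have columns start_s,end_s,label")
    intervals = [
        Interval(float(r.start_s), float(r.end_s), str(r.label)) for r in frame.itertuples()
    ]
    return AnnotationTrack(subject_id=meta.get("subject", ""), intervals=intervals)


def write_annotations(track: AnnotationTrack, path) -> None:
    path = Path(path)
    buf = _stdio.StringIO()
    if track.subject_id:
        buf.write(f"#subject={track.subject_id}\n")
    buf.write("start_s,end_s,label\n")
    for iv in track.intervals:
        buf.write(f"{iv.start_s:.15g},{iv.end_s:.15g},{iv.label}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

#: half-width of the windowed-sinc kernel, in source samples
SINC_HALF_WIDTH = 64


def _sinc_resample_matrix(x: np.ndarray, ratio: float, n_out: int) -> np.ndarray:
    """Hann-windowed sinc interpolation of columns of ``x`` at ``k / ratio``.

    ``ratio = target_rate / source_rate``. Edges use reflection padding; tap
    weights are normalized to unit sum so constants are preserved exactly.
    """
    half = SINC_HALF_WIDTH
    pad = half + 2
    xp = np.pad(x, ((pad, pad), (0, 0)), mode="reflect")
    d = np.arange(-half, half + 2)  # tap offsets around floor(u)
    out = np.empty((n_out, x.shape[1]))
    chunk = 8192
    for k0 in range(0, n_out, chunk):
        k = np.arange(k0, min(k0 + chunk, n_out))
        u = k / ratio
        c = np.floor(u).astype(np.int64)
        arg = d[None, :] - (u - c)[:, None]  # tap position minus fractional offset
        w = np.sinc(arg)
        taper = np.where(np.abs(arg) < half, 0.5 * (1.0 + np.cos(np.pi * arg / half)), 0.0)
        w *= taper
        w /= w.sum(axis=1, keepdims=True)
        idx = c[:, None] + d[None, :] + pad
        out[k0 : k0 + len(k)] = np.einsum("kt,ktc->kc", w, xp[idx])
    return out


def resample_sinc(rec: ImuRecording, target_rate: float) -> ImuRecording:
    """Downsample a recording to ``target_rate`` with a Hann-windowed sinc kernel.

    Output samples sit at ``t0_s + k / target_rate`` over the same time span as
    the input (any trailing partial sample is dropped). A recording already at
    the target rate is returned unchanged. Upsampling is not supported.
    """
    if target_rate > rec.rate_hz:
        raise UsageError(
            f"cannot upsample from {rec.rate_hz} Hz to {target_rate} Hz (downsampling only)"
        )
    if target_rate == rec.rate_hz:
        return rec
    ratio = target_rate / rec.rate_hz
    n_out = int(np.floor((rec.n_samples - 1) * ratio + 1e-9)) + 1
    gyro = _sinc_resample_matrix(rec.gyro, ratio, n_out)
    accel = None if rec.accel is None else _sinc_resample_matrix(rec.accel, ratio, n_out)
    return replace(rec, rate_hz=float(target_rate), gyro=gyro, accel=accel)
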