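"""Sample-wise agreement with expert annotations and percent of active time spent freezing.

Accuracy is the ratio of true positives plus true negatives to the total number
of compared samples; %ATSF is 100 x (time spent freezing) / (active time). Both
are computed over active (non-sedentary) samples only. Metrics that are
undefined on an input (no active samples, no reference FOG) are reported as
missing values, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityMask
from .errors import FormatError, UndefinedMetricError, UsageError
from .events import EventList, rasterize
from .io import AnnotationTrack


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(sensor, reference, mask: ActivityMask) -> ConfusionCounts:
    """Sample-wise confusion counts over active samples only."""
    sensor = np.asarray(sensor, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if sensor.size != reference.size or sensor.size != mask.n_samples:
        raise UsageError("sensor, reference and mask must have equal lengths")
    act = mask.flags
    s, r = sensor[act], reference[act]
    return ConfusionCounts(
        tp=int(np.sum(s & r)),
        tn=int(np.sum(~s & ~r)),
        fp=int(np.sum(s & ~r)),
        fn=int(np.sum(~s & r)),
    )


def accuracy_pct(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy is undefined with no compared samples")
    return 100.0 * (c.tp + c.tn) / c.total


def sensitivity_pct(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity is undefined with no reference FOG samples")
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity_pct(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity is undefined with no reference non-FOG samples")
    return 100.0 * c.tn / (c.tn + c.fp)


def atsf_pct(fog_flags, mask: ActivityMask) -> float:
    """Percent of active time spent freezing: 100 x active FOG samples / active samples."""
    fog_flags = np.asarray(fog_flags, dtype=bool)
    if fog_flags.size != mask.n_samples:
        raise UsageError("fog flags and activity mask differ in length")
    n_active = int(mask.flags.sum())
    if n_active == 0:
        raise UndefinedMetricError("%ATSF is undefined with no active samples")
    return 100.0 * int(np.sum(fog_flags & mask.flags)) / n_active


def mean_episode_duration(ev: EventList) -> float:
    """Arithmetic mean event duration in seconds."""
    if len(ev) == 0:
        raise UndefinedMetricError("mean episode duration is undefined for an empty event list")
    return float(ev.durations().mean())


def _safe(fn, *args) -> float:
    try:
        return fn(*args)
    except UndefinedMetricError:
        return math.nan


@dataclass
class TaskScore:
    """Metrics over one task's (or task group's) active samples; NaN = undefined."""

    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    sensor_atsf_pct: float
    video_atsf_pct: float
    n_active: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _score_submask(sensor, reference, submask: ActivityMask) -> TaskScore:
    c = confusion(sensor, reference, submask)
    return TaskScore(
        accuracy_pct=_safe(accuracy_pct, c),
        sensitivity_pct=_safe(sensitivity_pct, c),
        specificity_pct=_safe(specificity_pct, c),
        sensor_atsf_pct=_safe(atsf_pct, sensor, submask),
        video_atsf_pct=_safe(atsf_pct, reference, submask),
        n_active=int(submask.flags.sum()),
    )


def per_task_scores(
    sensor, reference, mask: ActivityMask, tasks: AnnotationTrack
) -> dict[str, TaskScore]:
    """Each metric computed over the active samples inside each task's intervals."""
    ivs = tasks.task_intervals()
    for a, b in zip(ivs, ivs[1:]):
        if b.start_s < a.end_s:
            raise FormatError("task intervals must be non-overlapping")
    out: dict[str, TaskScore] = {}
    for iv in ivs:
        name = iv.label.split(":", 1)[1]
        in_task = rasterize([(iv.start_s, iv.end_s)], mask.rate_hz, mask.t0_s, mask.n_samples)
        sub = ActivityMask(mask.rate_hz, mask.t0_s, mask.flags & in_task)
        out[name] = _score_submask(sensor, reference, sub)
    return out


def group_score(
    sensor, reference, mask: ActivityMask, tasks: AnnotationTrack, names
) -> TaskScore:
    """Metrics over the union of the named tasks' intervals (active samples only)."""
    ivs = [iv for iv in tasks.task_intervals() if iv.label.split(":", 1)[1] in set(names)]
    union = rasterize(
        [(iv.start_s, iv.end_s) for iv in ivs], mask.rate_hz, mask.t0_s, mask.n_samples
    )
    sub = ActivityMask(mask.rate_hz, mask.t0_s, mask.flags & union)
    return _score_submask(sensor, reference, sub)


@dataclass
class ScoreReport:
    """Visit-level score report: global metrics, an IADL aggregate, and per-task rows."""

    subject_id: str
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    sensor_atsf_pct: float
    video_atsf_pct: float
    mean_episode_s: float
    per_task: dict[str, TaskScore] = field(default_factory=dict)
    iadl: TaskScore | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "sensor_atsf_pct": self.sensor_atsf_pct,
            "video_atsf_pct": self.video_atsf_pct,
            "mean_episode_s": self.mean_episode_s,
            "per_task": {k: v.to_dict() for k, v in self.per_task.items()},
            "config": self.config,
        }
        if self.iadl is not None:
            d["iadl"] = self.iadl.to_dict()
        return d

    def per_task_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: v.to_dict() for k, v in self.per_task.items()}).T
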