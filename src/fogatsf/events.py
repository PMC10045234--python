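"""Binary detection series <-> FOG events: runs, merging, rasterization, restriction.

Events are half-open ``[start_s, end_s)`` intervals on the session clock.
Detector events separated by less than 2 s are merged into single FOG events;
the same half-open sample-inclusion rule (``start <= t_k < end``) is applied to
detector events and rater annotations so both rasterize identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityMask
from .errors import UsageError
from .io import AnnotationTrack

DEFAULT_MERGE_GAP_S = 2.0

#: float guard when mapping interval edges to sample indices, in sample units
_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class FogEvent:
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise UsageError(f"event end {self.end_s} must exceed start {self.start_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EventList:
    """Sorted, non-overlapping FOG events."""

    events: list[FogEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        ev = sorted(self.events, key=lambda e: e.start_s)
        for prev, cur in zip(ev, ev[1:]):
            if cur.start_s < prev.end_s:
                raise UsageError("events must be non-overlapping")
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def durations(self) -> np.ndarray:
        return np.array([e.duration_s for e in self.events])

    def total_s(self) -> float:
        return float(self.durations().sum()) if self.events else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [e.start_s for e in self.events],
                "end_s": [e.end_s for e in self.events],
                "duration_s": [e.duration_s for e in self.events],
            }
        )


def series_to_events(flags, rate_hz: float, t0_s: float) -> EventList:
    """Maximal runs of True become events; end is the timestamp *after* the last
    True sample (half-open convention)."""
    flags = np.asarray(flags, dtype=bool)
    if flags.ndim != 1 or flags.size < 1:
        raise UsageError("flags must be a non-empty 1-d boolean array")
    padded = np.concatenate([[False], flags, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # index one past the last True sample
    return EventList(
        [FogEvent(t0_s + s / rate_hz, t0_s + e / rate_hz) for s, e in zip(starts, ends)]
    )


def merge_events(ev: EventList, gap_s: float = DEFAULT_MERGE_GAP_S) -> EventList:
    """Union consecutive events whose separating gap is strictly less than ``gap_s``.

    Applied transitively; idempotent. A gap of exactly ``gap_s`` is kept.
    """
    if len(ev) == 0:
        return EventList([])
    merged: list[FogEvent] = [ev[0]]
    for cur in ev[1:]:
        prev = merged[-1]
        if cur.start_s - prev.end_s < gap_s:
            merged[-1] = FogEvent(prev.start_s, max(prev.end_s, cur.end_s))
        else:
            merged.append(cur)
    return EventList(merged)


def _as_intervals(track_or_events) -> list[tuple[float, float]]:
    if isinstance(track_or_events, AnnotationTrack):
        return [(iv.start_s, iv.end_s) for iv in track_or_events.fog_intervals()]
    if isinstance(track_or_events, EventList):
        return [(e.start_s, e.end_s) for e in track_or_events]
    return [(float(s), float(e)) for s, e in track_or_events]


def rasterize(track_or_events, rate_hz: float, t0_s: float, n: int) -> np.ndarray:
    """Per-sample booleans: sample k is True iff ``start <= t_k < end`` for some
    interval, with ``t_k = t0_s + k / rate_hz``."""
    if n < 1:
        raise UsageError("n must be at least 1")
    flags = np.zeros(n, dtype=bool)
    for start, end in _as_intervals(track_or_events):
        k0 = int(np.ceil((start - t0_s) * rate_hz - _EDGE_EPS))
        k1 = int(np.ceil((end - t0_s) * rate_hz - _EDGE_EPS))  # first sample at/after end
        k0, k1 = max(k0, 0), min(k1, n)
        if k1 > k0:
            flags[k0:k1] = True
    return flags


def restrict_active(flags, mask: ActivityMask) -> tuple[np.ndarray, np.ndarray]:
    """Subsequence of ``flags`` at active samples, with the index map retained.

    Returns ``(values, indices)`` where ``indices`` are the positions of the
    active samples in the original series.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size != mask.n_samples:
        raise UsageError("flags and activity mask differ in length")
    idx = np.flatnonzero(mask.flags)
    return flags[idx], idx
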