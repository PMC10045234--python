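"""Synthetic multi-sensor IMU cohort with ground-truth FOG annotations.

The study's patient recordings are not publicly deposited, so this module
generates the inputs the pipeline consumes: tri-axial gyro/accel streams at
100 Hz for left foot, right foot and left hip, with exact ground-truth FOG
intervals, a session plan of clinic gait tasks, simulated IADL tasks and home
wear, and an imperfect-rater emulation standing in for expert video review.

The signal model is deliberately minimal (piecewise-stationary oscillators plus
sensor noise), built to exercise every pipeline branch rather than to be
biomechanically faithful:

* walking: alternating half-sine foot swing pulses at the stepping cadence with
  a continuously moving hip;
* trembling FOG: 5 Hz foot oscillation without progression, hip still active;
* akinetic FOG: near-zero foot motion, hip still active;
* sitting: hip near zero with occasional 2 Hz leg-bounce bursts on one foot.

FOG episodes arrive as a Poisson process during movement segments with rate
proportional to the subject's severity; durations are log-normal with a 5 s
mean. Everything is deterministic for a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UsageError
from .io import (
    FOG_LABEL,
    TASK_PREFIX,
    AnnotationTrack,
    ImuRecording,
    Interval,
    write_annotations,
    write_imu,
)

SAMPLE_RATE_HZ = 100.0
MOVEMENT_KINDS = ("walk_task", "iadl_task", "home_mixed")
SEGMENT_KINDS = MOVEMENT_KINDS + ("sitting",)

#: gyro sensor noise (deg/s, per axis). Chosen so the rectified-noise floor of
#: the summed hip angular speed (3 * sigma * sqrt(2/pi) ~ 0.48 deg/s) stays
#: below the 1 deg/s sedentary threshold, as it must for real hardware whose
#: quiet-sitting output is classified sedentary.
GYRO_NOISE_DPS = 0.2
ACCEL_NOISE_G = 0.02

SWING_DURATION_S = 0.3
TREMBLE_FREQ_HZ = 5.0
TREMBLE_AMP_DPS = 25.0
AKINETIC_AMP_DPS = 0.5  # residual foot motion during akinetic freezes
HIP_BASE_DPS = 10.0
HIP_SWAY_DPS = 6.0
SIT_HIP_AMP_DPS = 0.2
BOUNCE_RATE_PER_MIN = 2.0
BOUNCE_FREQ_HZ = 2.0
BOUNCE_AMP_DPS = 20.0
MIN_EPISODE_S = 0.3  # slivers clipped at a segment end below this are dropped


@dataclass(frozen=True)
class Segment:
    name: str
    kind: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise UsageError(f"unknown segment kind {self.kind!r}")
        if not self.duration_s > 0:
            raise UsageError("segment durations must be positive")


@dataclass
class SessionPlan:
    """Ordered segments of one recording session."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise UsageError("segment names must be unique within a session")

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def bounds(self) -> list[tuple[float, float, Segment]]:
        out, t = [], 0.0
        for seg in self.segments:
            out.append((t, t + seg.duration_s, seg))
            t += seg.duration_s
        return out

    def tasks(self) -> AnnotationTrack:
        """Task intervals (``task:<name>`` labels) spanning each segment."""
        return AnnotationTrack(
            intervals=[
                Interval(a, b, TASK_PREFIX + seg.name) for a, b, seg in self.bounds()
            ]
        )


def default_plans(duration_scale: float = 1.0) -> dict[str, SessionPlan]:
    """The in-person visit and 3-day home-wear session plans.

    Visit: three clinic gait tasks (120 s each), the vacuum/dish/community
    IADL tasks (180 s each) and a 600 s sitting task (the protocol's "at least
    ten minutes"). Home: three desk-scale days of alternating mixed household
    movement and sitting, ~30 min per day. ``duration_scale`` shrinks every
    segment proportionally for quick experiments.
    """
    s = duration_scale

    def seg(name, kind, dur):
        return Segment(name, kind, dur * s)

    visit = SessionPlan(
        [
            seg("hallway_pivot", "walk_task", 120.0),
            seg("go_outside_turn", "walk_task", 120.0),
            seg("turn_360", "walk_task", 120.0),
            seg("vacuum", "iadl_task", 180.0),
            seg("dish", "iadl_task", 180.0),
            seg("sitting", "sitting", 600.0),
            seg("community", "iadl_task", 180.0),
        ]
    )
    home_segments = []
    for day in (1, 2, 3):
        home_segments += [
            seg(f"d{day}_active_am", "home_mixed", 600.0),
            seg(f"d{day}_rest_am", "sitting", 300.0),
            seg(f"d{day}_active_pm", "home_mixed", 600.0),
            seg(f"d{day}_rest_pm", "sitting", 300.0),
        ]
    return {"visit": visit, "home": SessionPlan(home_segments)}


IADL_TASKS = ("vacuum", "dish", "sitting", "community")
CLINIC_TASKS = ("hallway_pivot", "go_outside_turn", "turn_360")


@dataclass
class SubjectProfile:
    """Per-subject generative parameters.

    ``severity`` in [0, 1] drives the FOG episode rate
    (``fog_base_rate_per_min * severity`` episodes per active minute).
    """

    subject_id: str
    severity: float
    cadence_hz: float = 1.8
    swing_amp_dps: float = 200.0
    fog_base_rate_per_min: float = 1.5
    episode_mean_s: float = 5.0
    episode_sigma_log: float = 0.5
    trembling_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise UsageError("severity must lie in [0, 1]")
        for name in ("cadence_hz", "swing_amp_dps", "fog_base_rate_per_min",
                     "episode_mean_s", "episode_sigma_log"):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be non-negative")
        if not 0.0 <= self.trembling_fraction <= 1.0:
            raise UsageError("trembling_fraction must lie in [0, 1]")

    @property
    def fog_rate_per_min(self) -> float:
        return self.fog_base_rate_per_min * self.severity


def nfogq_like(severity: float, rng: np.random.Generator) -> int:
    """Noise-dominated questionnaire analog on the 0-28 scale.

    Deliberately weakly informative about severity (weight 0.3 signal, 0.7
    uniform noise) so the cohort analysis can demonstrate the dissociation
    between self-report and objective FOG measures.
    """
    u = rng.uniform()
    return int(np.clip(round(28.0 * (0.3 * severity + 0.7 * u)), 0, 28))


def draw_episodes(
    rng: np.random.Generator, start_s: float, end_s: float, profile: SubjectProfile
) -> list[tuple[float, float, str]]:
    """Poisson FOG arrivals with log-normal durations inside one movement segment.

    Durations have mean ``episode_mean_s`` (log-normal with shape
    ``episode_sigma_log``); episodes never overlap (arrivals resume after each
    episode ends) and are clipped at the segment end.
    """
    lam = profile.fog_rate_per_min / 60.0
    if lam <= 0:
        return []
    mu = np.log(profile.episode_mean_s) - profile.episode_sigma_log**2 / 2.0
    out: list[tuple[float, float, str]] = []
    t = start_s
    while True:
        t += rng.exponential(1.0 / lam)
        if t >= end_s:
            break
        dur = rng.lognormal(mu, profile.episode_sigma_log)
        kind = "trembling" if rng.uniform() < profile.trembling_fraction else "akinetic"
        end = min(t + dur, end_s)
        if end - t >= MIN_EPISODE_S:
            out.append((t, end, kind))
        t = end
    return out


@dataclass
class SimulatedSession:
    """One session's three recordings plus exact truth and the task plan."""

    left_foot: ImuRecording
    right_foot: ImuRecording
    left_hip: ImuRecording
    truth: AnnotationTrack
    tasks: AnnotationTrack
    episodes: list[tuple[float, float, str]] = field(default_factory=list)

    def recordings(self) -> dict[str, ImuRecording]:
        return {
            "left_foot": self.left_foot,
            "right_foot": self.right_foot,
            "left_hip": self.left_hip,
        }


def _walking_foot(t_rel: np.ndarray, cadence_hz: float, amp: float, phase: float) -> np.ndarray:
    """Half-sine swing pulse train for one foot (per-foot rate = cadence / 2)."""
    period = 2.0 / cadence_hz
    ph = np.mod(t_rel - phase * period, period)
    return np.where(ph < SWING_DURATION_S, amp * np.sin(np.pi * ph / SWING_DURATION_S), 0.0)


def simulate_session(
    profile: SubjectProfile, plan: SessionPlan, seed
) -> SimulatedSession:
    """Generate one session's left-foot/right-foot/left-hip streams at 100 Hz.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`. All
    output is byte-deterministic for a fixed seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ep_rng, bounce_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    fs = SAMPLE_RATE_HZ
    n = int(round(plan.total_duration_s * fs))
    t = np.arange(n) / fs
    gyro = {site: np.zeros((n, 3)) for site in ("left_foot", "right_foot", "left_hip")}
    accel = {site: np.zeros((n, 3)) for site in ("left_foot", "right_foot", "left_hip")}
    episodes: list[tuple[float, float, str]] = []

    for seg_start, seg_end, seg in plan.bounds():
        k0, k1 = int(round(seg_start * fs)), int(round(seg_end * fs))
        tt = t[k0:k1] - seg_start
        if seg.kind in MOVEMENT_KINDS:
            gyro["left_foot"][k0:k1, 1] = _walking_foot(tt, profile.cadence_hz,
                                                        profile.swing_amp_dps, 0.0)
            gyro["right_foot"][k0:k1, 1] = _walking_foot(tt, profile.cadence_hz,
                                                         profile.swing_amp_dps, 0.5)
            gyro["left_hip"][k0:k1, 0] = HIP_BASE_DPS + HIP_SWAY_DPS * np.sin(
                2 * np.pi * profile.cadence_hz * tt
            )
            for site in ("left_foot", "right_foot", "left_hip"):
                accel[site][k0:k1, 2] = 1.0 + 0.1 * np.sin(2 * np.pi * profile.cadence_hz * tt)
            episodes.extend(draw_episodes(ep_rng, seg_start, seg_end, profile))
        else:  # sitting
            gyro["left_hip"][k0:k1, 0] = SIT_HIP_AMP_DPS * np.sin(2 * np.pi * 0.3 * tt)
            for site in ("left_foot", "right_foot", "left_hip"):
                accel[site][k0:k1, 2] = 1.0
            # occasional one-foot leg bounce while seated
            bt = seg_start
            while True:
                bt += bounce_rng.exponential(60.0 / BOUNCE_RATE_PER_MIN)
                if bt >= seg_end:
                    break
                b_end = min(bt + bounce_rng.uniform(2.0, 5.0), seg_end)
                foot = "left_foot" if bounce_rng.uniform() < 0.5 else "right_foot"
                j0, j1 = int(round(bt * fs)), int(round(b_end * fs))
                gyro[foot][j0:j1, 1] = BOUNCE_AMP_DPS * np.sin(
                    2 * np.pi * BOUNCE_FREQ_HZ * (t[j0:j1] - bt)
                )
                bt = b_end

    # overwrite foot channels inside FOG episodes (hip stays active)
    for a, b, kind in episodes:
        j0, j1 = int(round(a * fs)), int(round(b * fs))
        for site in ("left_foot", "right_foot"):
            gyro[site][j0:j1, :] = 0.0
            if kind == "trembling":
                gyro[site][j0:j1, 1] = TREMBLE_AMP_DPS * np.sin(
                    2 * np.pi * TREMBLE_FREQ_HZ * (t[j0:j1] - a)
                )
            else:
                gyro[site][j0:j1, 1] = AKINETIC_AMP_DPS * np.sin(
                    2 * np.pi * 0.5 * (t[j0:j1] - a)
                )

    recs = {}
    for site in ("left_foot", "right_foot", "left_hip"):
        g = gyro[site] + noise_rng.normal(0.0, GYRO_NOISE_DPS, (n, 3))
        a_ = accel[site] + noise_rng.normal(0.0, ACCEL_NOISE_G, (n, 3))
        recs[site] = ImuRecording(
            subject_id=profile.subject_id, site=site, rate_hz=fs, t0_s=0.0, gyro=g, accel=a_
        )

    truth = AnnotationTrack(
        subject_id=profile.subject_id,
        intervals=[Interval(a, b, FOG_LABEL) for a, b, _ in episodes],
    )
    tasks = replace(plan.tasks(), subject_id=profile.subject_id)
    return SimulatedSession(
        left_foot=recs["left_foot"],
        right_foot=recs["right_foot"],
        left_hip=recs["left_hip"],
        truth=truth,
        tasks=tasks,
        episodes=sorted(episodes),
    )


def emulate_rater(
    truth: AnnotationTrack,
    jitter_sd_s: float = 0.2,
    min_episode_s: float = 0.5,
    seed=0,
) -> AnnotationTrack:
    """Imperfect human rater: Gaussian boundary jitter plus a perception floor.

    Each FOG boundary is perturbed by N(0, ``jitter_sd_s``^2) (two draws per
    episode, start then end, in episode order); starts are clipped at 0 and
    ends clipped to keep start < end. Episodes shorter than ``min_episode_s``
    are dropped as imperceptible. The output is normalized.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    out: list[Interval] = []
    for iv in truth.fog_intervals():
        ds, de = rng.normal(0.0, jitter_sd_s, 2) if jitter_sd_s > 0 else (0.0, 0.0)
        s = max(0.0, iv.start_s + ds)
        e = max(s + 1e-6, iv.end_s + de)
        if e - s >= max(min_episode_s, 1e-6):
            out.append(Interval(s, e, FOG_LABEL))
    return AnnotationTrack(subject_id=truth.subject_id, intervals=out)


def cohort_severities(n: int) -> np.ndarray:
    """Severities spaced over [0, 1] with two FOG-free subjects.

    Mirrors the study cohort, in which two of the 19 participants had no
    observed FOG during the visit.
    """
    if n < 3:
        raise UsageError("a cohort needs at least 3 subjects")
    graded = np.arange(1, n - 1) / (n - 2)
    return np.concatenate([[0.0, 0.0], graded])


def build_profiles(n: int, seed: int) -> tuple[list[SubjectProfile], dict[str, int]]:
    """Profiles plus per-subject questionnaire scores for an ``n``-subject cohort."""
    sev = cohort_severities(n)
    profiles, nfogq = [], {}
    for i, s in enumerate(sev):
        sid = f"subj{i:02d}"
        profiles.append(SubjectProfile(subject_id=sid, severity=float(s)))
        nfogq[sid] = nfogq_like(
            float(s), np.random.default_rng(np.random.SeedSequence([seed, i, 3]))
        )
    return profiles, nfogq


def iter_cohort(
    n: int = 19,
    seed: int = 7,
    plans: dict[str, SessionPlan] | None = None,
    include_home: bool = True,
    jitter_sd_s: float = 0.2,
    min_episode_s: float = 0.5,
):
    """Lazily generate per-subject bundles (profile, visit, rater, home, nfogq).

    Per-subject randomness is derived counter-style from ``(seed, subject
    index, stream)`` so any single artifact is independently replayable.
    """
    plans = plans or default_plans()
    profiles, nfogq = build_profiles(n, seed)
    for i, profile in enumerate(profiles):
        visit = simulate_session(profile, plans["visit"], np.random.SeedSequence([seed, i, 0]))
        rater = emulate_rater(
            visit.truth, jitter_sd_s, min_episode_s, np.random.SeedSequence([seed, i, 2])
        )
        home = None
        if include_home:
            home = simulate_session(
                profile, plans["home"], np.random.SeedSequence([seed, i, 1])
            )
        yield {
            "profile": profile,
            "visit": visit,
            "rater": rater,
            "home": home,
            "nfogq": nfogq[profile.subject_id],
        }


def simulate_cohort(
    n: int = 19,
    seed: int = 7,
    out_dir=None,
    plans: dict[str, SessionPlan] | None = None,
    include_home: bool = True,
) -> pd.DataFrame:
    """Generate a cohort and (optionally) write the file tree the pipeline consumes.

    Layout under ``out_dir``: ``<subject>/visit/{left_foot,right_foot,
    left_hip,truth,rater,tasks}.csv`` and ``<subject>/home/...``. Returns the
    cohort table of true burdens (severity, questionnaire score, true FOG
    seconds in the visit).
    """
    rows = []
    for bundle in iter_cohort(n=n, seed=seed, plans=plans, include_home=include_home):
        profile, visit = bundle["profile"], bundle["visit"]
        if out_dir is not None:
            sdir = Path(out_dir) / profile.subject_id
            vdir = sdir / "visit"
            vdir.mkdir(parents=True, exist_ok=True)
            for site, rec in visit.recordings().items():
                write_imu(rec, vdir / f"{site}.csv")
            write_annotations(visit.truth, vdir / "truth.csv")
            write_annotations(bundle["rater"], vdir / "rater.csv")
            write_annotations(visit.tasks, vdir / "tasks.csv")
            if bundle["home"] is not None:
                hdir = sdir / "home"
                hdir.mkdir(parents=True, exist_ok=True)
                for site, rec in bundle["home"].recordings().items():
                    write_imu(rec, hdir / f"{site}.csv")
        rows.append(
            {
                "subject_id": profile.subject_id,
                "severity": profile.severity,
                "nfogq": bundle["nfogq"],
                "true_fog_visit_s": visit.truth.total_fog_s(),
                "n_true_episodes_visit": len(visit.truth.fog_intervals()),
            }
        )
    table = pd.DataFrame(rows).set_index("subject_id")
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "cohort_truth.csv")
    return table
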