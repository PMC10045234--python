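"""End-to-end orchestration: resample -> mask -> detect -> merge -> score -> correlate.

One :class:`PipelineConfig` houses every analysis constant: the 100 Hz analysis
rate, the 0.7 pFOG threshold, the <2 s event merge, and the 1 deg/s / 20 s
sedentary rule. Visit scoring is task-restricted (samples outside the clinic
gait and simulated IADL task intervals are dropped); event merging happens on
the full timeline before the active-time restriction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .activity import ActivityMask, compute_activity_mask
from .detect import DetectorConfig, combine_feet, detect_foot
from .errors import UndefinedMetricError, UsageError
from .events import merge_events, rasterize, series_to_events
from .io import AnnotationTrack, ImuRecording, read_annotations, read_imu, resample_sinc
from .score import ScoreReport, _safe, atsf_pct, group_score, per_task_scores
from .score import accuracy_pct, confusion, mean_episode_duration, sensitivity_pct, specificity_pct
from .simulate import IADL_TASKS, SessionPlan, iter_cohort
from .stats import correlation_matrix
from .events import EventList, FogEvent

logger = logging.getLogger("fogatsf")

SITE_FILES = ("left_foot", "right_foot", "left_hip")


@dataclass
class PipelineConfig:
    """All analysis constants of the assessment pipeline."""

    target_rate_hz: float = 100.0
    pfog_threshold: float = 0.7
    merge_gap_s: float = 2.0
    activity_threshold_dps: float = 1.0
    activity_window_s: float = 20.0
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    rater_jitter_sd_s: float = 0.2
    rater_min_episode_s: float = 0.5
    pool_home_days: bool = True

    def __post_init__(self) -> None:
        for name in ("target_rate_hz", "merge_gap_s", "activity_threshold_dps",
                     "activity_window_s"):
            if not getattr(self, name) > 0:
                raise UsageError(f"{name} must be positive")
        if not 0.0 < self.pfog_threshold < 1.0:
            raise UsageError("pfog_threshold must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detector"]["emit"] = np.asarray(d["detector"]["emit"]).tolist()
        d["version"] = __version__
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectorConfig(**raw.pop("detector", {}))
        return cls(detector=det, **raw)


@dataclass
class DetectionResult:
    """Intermediate products of one session's detection pass."""

    mask: ActivityMask
    fog_flags: np.ndarray  # per-sample, after merging, full timeline
    events: EventList  # merged sensor events
    n_samples: int
    rate_hz: float
    t0_s: float


def detect_session(
    left: ImuRecording, right: ImuRecording, hip: ImuRecording, cfg: PipelineConfig
) -> DetectionResult:
    """Resample to the analysis rate, mask sedentary time, detect and merge FOG events."""
    left = resample_sinc(left, cfg.target_rate_hz)
    right = resample_sinc(right, cfg.target_rate_hz)
    hip = resample_sinc(hip, cfg.target_rate_hz)
    n = min(left.n_samples, right.n_samples, hip.n_samples)

    def _trim(rec: ImuRecording) -> ImuRecording:
        if rec.n_samples == n:
            return rec
        # tolerate off-by-a-sample download lengths between sites
        return dataclasses.replace(
            rec, gyro=rec.gyro[:n], accel=None if rec.accel is None else rec.accel[:n]
        )

    left, right, hip = _trim(left), _trim(right), _trim(hip)
    mask = compute_activity_mask(hip, cfg.activity_threshold_dps, cfg.activity_window_s)
    trace_l = detect_foot(left, cfg.detector)
    trace_r = detect_foot(right, cfg.detector)
    raw_flags = combine_feet(trace_l, trace_r, cfg.pfog_threshold)
    events = merge_events(
        series_to_events(raw_flags, left.rate_hz, left.t0_s), cfg.merge_gap_s
    )
    fog_flags = rasterize(events, left.rate_hz, left.t0_s, n)
    logger.info(
        "detected %d raw FOG samples -> %d merged events (%.1f s) over %d samples, "
        "%.1f s active",
        int(raw_flags.sum()), len(events), events.total_s(), n, mask.active_seconds,
    )
    return DetectionResult(
        mask=mask, fog_flags=fog_flags, events=events,
        n_samples=n, rate_hz=left.rate_hz, t0_s=left.t0_s,
    )


def _task_union(tasks: AnnotationTrack, det: DetectionResult, names=None) -> np.ndarray:
    ivs = tasks.task_intervals()
    if names is not None:
        names = set(names)
        ivs = [iv for iv in ivs if iv.label.split(":", 1)[1] in names]
    return rasterize(
        [(iv.start_s, iv.end_s) for iv in ivs], det.rate_hz, det.t0_s, det.n_samples
    )


def score_visit_session(
    left: ImuRecording,
    right: ImuRecording,
    hip: ImuRecording,
    rater: AnnotationTrack,
    tasks: AnnotationTrack,
    cfg: PipelineConfig | None = None,
) -> ScoreReport:
    """Score one in-person visit against rater annotations.

    Global metrics cover the active samples inside all task intervals; the
    ``iadl`` aggregate covers the four simulated-IADL tasks; ``per_task``
    holds one row per task. ``mean_episode_s`` is the mean duration of the
    rater's FOG episodes intersecting the analyzed task region (episode
    durations are an expert-review quantity).
    """
    cfg = cfg or PipelineConfig()
    det = detect_session(left, right, hip, cfg)
    video = rasterize(rater, det.rate_hz, det.t0_s, det.n_samples)
    in_tasks = _task_union(tasks, det)
    analysis = ActivityMask(det.rate_hz, det.t0_s, det.mask.flags & in_tasks)
    c = confusion(det.fog_flags, video, analysis)
    # episode durations follow expert review (the rater track), not the detector
    rater_events = EventList(
        [
            FogEvent(iv.start_s, iv.end_s)
            for iv in rater.fog_intervals()
            if rasterize([(iv.start_s, iv.end_s)], det.rate_hz, det.t0_s, det.n_samples)[
                in_tasks
            ].any()
        ]
    )
    report = ScoreReport(
        subject_id=left.subject_id,
        accuracy_pct=_safe(accuracy_pct, c),
        sensitivity_pct=_safe(sensitivity_pct, c),
        specificity_pct=_safe(specificity_pct, c),
        sensor_atsf_pct=_safe(atsf_pct, det.fog_flags, analysis),
        video_atsf_pct=_safe(atsf_pct, video, analysis),
        mean_episode_s=_safe(mean_episode_duration, rater_events),
        per_task=per_task_scores(det.fog_flags, video, det.mask, tasks),
        iadl=group_score(det.fog_flags, video, det.mask, tasks, IADL_TASKS),
        config=cfg.to_dict(),
    )
    return report


def _load_sites(directory: Path) -> dict[str, ImuRecording]:
    recs = {}
    for site in SITE_FILES:
        path = directory / f"{site}.csv"
        if not path.exists():
            raise UsageError(f"missing site file {path}")
        recs[site] = read_imu(path)
    return recs


def run_visit(subject_dir, cfg: PipelineConfig | None = None, out_path=None) -> ScoreReport:
    """Score the in-person visit stored under ``<subject_dir>/visit/``."""
    cfg = cfg or PipelineConfig()
    vdir = Path(subject_dir) / "visit"
    recs = _load_sites(vdir)
    rater = read_annotations(vdir / "rater.csv")
    tasks = read_annotations(vdir / "tasks.csv")
    report = score_visit_session(
        recs["left_foot"], recs["right_foot"], recs["left_hip"], rater, tasks, cfg
    )
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return report


def home_atsf(
    left: ImuRecording, right: ImuRecording, hip: ImuRecording, cfg: PipelineConfig | None = None
) -> float:
    """Sensor %ATSF over one home recording (no annotations required)."""
    cfg = cfg or PipelineConfig()
    det = detect_session(left, right, hip, cfg)
    return atsf_pct(det.fog_flags, det.mask)  # raises UndefinedMetricError if all sedentary


def run_home(subject_dir, cfg: PipelineConfig | None = None) -> float:
    """Pooled sensor %ATSF over the home recordings under ``<subject_dir>/home/``."""
    cfg = cfg or PipelineConfig()
    hdir = Path(subject_dir) / "home"
    recs = _load_sites(hdir)
    return home_atsf(recs["left_foot"], recs["right_foot"], recs["left_hip"], cfg)


VISIT_COLUMNS = ["nfogq", "sensor_atsf_visit", "video_atsf_visit", "sensor_atsf_home"]
IADL_COLUMNS = ["nfogq", "sensor_atsf_iadl", "video_atsf_iadl", "sensor_atsf_home"]


def _cohort_row(report: ScoreReport, home: float, nfogq: float) -> dict:
    return {
        "nfogq": nfogq,
        "sensor_atsf_visit": report.sensor_atsf_pct,
        "video_atsf_visit": report.video_atsf_pct,
        "sensor_atsf_iadl": report.iadl.sensor_atsf_pct if report.iadl else np.nan,
        "video_atsf_iadl": report.iadl.video_atsf_pct if report.iadl else np.nan,
        "sensor_atsf_home": home,
        "accuracy_visit_pct": report.accuracy_pct,
        "accuracy_iadl_pct": report.iadl.accuracy_pct if report.iadl else np.nan,
        "mean_episode_s": report.mean_episode_s,
    }


def _mean_sd_n(values) -> dict:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return {
        "mean_pct": v.mean() if v.size else np.nan,
        "sd_pct": v.std(ddof=1) if v.size > 1 else np.nan,
        "n": v.size,
    }


def _summaries(cohort: pd.DataFrame, reports: list[ScoreReport]):
    acc_rows = {}
    task_names = sorted({t for r in reports for t in r.per_task})
    for name in task_names:
        acc_rows[name] = [r.per_task[name].accuracy_pct for r in reports if name in r.per_task]
    acc_rows["visit"] = cohort["accuracy_visit_pct"].to_numpy()
    accuracy_summary = pd.DataFrame({k: _mean_sd_n(v) for k, v in acc_rows.items()}).T
    atsf_cols = [c for c in cohort.columns if "atsf" in c]
    atsf_summary = pd.DataFrame({c: _mean_sd_n(cohort[c]) for c in atsf_cols}).T
    return accuracy_summary, atsf_summary


def run_cohort(root, cfg: PipelineConfig | None = None, out_dir=None) -> dict:
    """Process every subject directory under ``root``: reports, cohort table, matrices.

    Subjects that fail to process are logged and reported as missing rows.
    Writes ``cohort_table.csv``, ``accuracy_summary.csv``, ``atsf_summary.csv``,
    ``corr_visit.csv`` and ``corr_iadl.csv`` under ``out_dir`` when given.
    """
    cfg = cfg or PipelineConfig()
    root = Path(root)
    truth_path = root / "cohort_truth.csv"
    nfogq = {}
    if truth_path.exists():
        tt = pd.read_csv(truth_path).set_index("subject_id")
        if "nfogq" in tt.columns:
            nfogq = tt["nfogq"].to_dict()
    subject_dirs = sorted(d for d in root.iterdir() if (d / "visit").is_dir())
    if len(subject_dirs) < 3:
        raise UsageError("cohort analysis needs at least 3 processed subjects")
    rows, reports = {}, []
    for sdir in subject_dirs:
        try:
            report = run_visit(sdir, cfg)
            home = np.nan
            if (sdir / "home").is_dir():
                try:
                    home = run_home(sdir, cfg)
                except UndefinedMetricError:
                    logger.warning("%s: no active home time; home %%ATSF undefined", sdir.name)
            reports.append(report)
            rows[sdir.name] = _cohort_row(report, home, nfogq.get(sdir.name, np.nan))
        except Exception:
            logger.warning("subject %s failed; reported as missing", sdir.name, exc_info=True)
            rows[sdir.name] = {}
    cohort = pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject_id")
    corr_visit = correlation_matrix(cohort, [c for c in VISIT_COLUMNS if c in cohort])
    corr_iadl = correlation_matrix(cohort, [c for c in IADL_COLUMNS if c in cohort])
    accuracy_summary, atsf_summary = _summaries(cohort, reports)
    result = {
        "cohort_table": cohort,
        "corr_visit": corr_visit,
        "corr_iadl": corr_iadl,
        "accuracy_summary": accuracy_summary,
        "atsf_summary": atsf_summary,
        "config": cfg.to_dict(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort_table.csv")
        accuracy_summary.to_csv(out / "accuracy_summary.csv")
        atsf_summary.to_csv(out / "atsf_summary.csv")
        corr_visit.to_csv(out / "corr_visit.csv")
        corr_iadl.to_csv(out / "corr_iadl.csv")
        (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))
    return result


def evaluate_synthetic_cohort(
    n: int = 19,
    seed: int = 7,
    cfg: PipelineConfig | None = None,
    plans: dict[str, SessionPlan] | None = None,
    include_home: bool = False,
) -> tuple[pd.DataFrame, list[ScoreReport]]:
    """Simulate an ``n``-subject cohort in memory and score every visit.

    Returns the cohort table (one row per subject: questionnaire score, sensor
    and video %ATSF for visit and IADL portions, accuracies, plus the
    ground-truth %ATSF computed from the injected episodes) and the per-subject
    score reports. This is the package's simulation analog of the study: the
    synthetic rater stands in for expert video review.
    """
    cfg = cfg or PipelineConfig()
    rows, reports = {}, []
    for bundle in iter_cohort(
        n=n,
        seed=seed,
        plans=plans,
        include_home=include_home,
        jitter_sd_s=cfg.rater_jitter_sd_s,
        min_episode_s=cfg.rater_min_episode_s,
    ):
        visit, profile = bundle["visit"], bundle["profile"]
        report = score_visit_session(
            visit.left_foot, visit.right_foot, visit.left_hip, bundle["rater"], visit.tasks, cfg
        )
        home = np.nan
        if bundle["home"] is not None:
            h = bundle["home"]
            try:
                home = home_atsf(h.left_foot, h.right_foot, h.left_hip, cfg)
            except UndefinedMetricError:
                home = np.nan
        row = _cohort_row(report, home, bundle["nfogq"])
        # ground-truth burden over the same analysis region (active task samples)
        det_rate = cfg.target_rate_hz
        n_samp = visit.left_hip.n_samples
        mask = compute_activity_mask(
            visit.left_hip, cfg.activity_threshold_dps, cfg.activity_window_s
        )
        in_tasks = rasterize(
            [(iv.start_s, iv.end_s) for iv in visit.tasks.task_intervals()],
            det_rate, 0.0, n_samp,
        )
        analysis = ActivityMask(det_rate, 0.0, mask.flags & in_tasks)
        truth_raster = rasterize(visit.truth, det_rate, 0.0, n_samp)
        row["true_atsf_visit"] = _safe(atsf_pct, truth_raster, analysis)
        row["severity"] = profile.severity
        rows[profile.subject_id] = row
        reports.append(report)
        logger.info(
            "%s: severity %.2f, accuracy %.1f%%, sensor/video %%ATSF %.2f/%.2f",
            profile.subject_id, profile.severity, report.accuracy_pct,
            report.sensor_atsf_pct, report.video_atsf_pct,
        )
    cohort = pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject_id")
    return cohort, reports
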