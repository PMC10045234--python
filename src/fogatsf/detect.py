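"""Per-foot FOG probability via a two-stage detector and forward probability filter.

Structure: per-sample *zero-velocity* flags (windowed RMS of foot angular rate
below a stance-like floor) and *trembling* flags (freeze-band 3-8 Hz power
dominating locomotor-band 0.5-3 Hz power in a sliding spectral window) are the
observations of a two-state hidden process {noFOG, FOG}. A causal normalized
forward recursion turns the observation pair at each sample into the posterior
probability of FOG (pFOG); FOG is called where pFOG for either foot exceeds a
0.7 threshold.

This is an explicit stand-in for the published pFOG detector, preserving its
documented two-stage-events -> probability-filter -> threshold structure; all
stand-in parameters live in :class:`DetectorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError
from .io import ImuRecording

FOOT_SITES = ("left_foot", "right_foot")

#: default emission table P(observation | state); rows: noFOG, FOG; columns
#: index the observation pair (zv, tremble) as (0,0), (1,0), (0,1), (1,1).
DEFAULT_EMISSIONS = np.array(
    [
        [0.60, 0.25, 0.10, 0.05],
        [0.10, 0.20, 0.20, 0.50],
    ]
)


@dataclass
class DetectorConfig:
    """Tunable parameters of the stand-in detector.

    Units: windows in seconds, angular rates in deg/s, band powers in (deg/s)^2.
    ``persist`` is the per-sample self-transition probability of the hidden
    state; ``pfog_threshold`` is the supra-threshold level that defines FOG.
    """

    zv_window_s: float = 0.25
    zv_rms_dps: float = 10.0
    fi_window_s: float = 2.0
    freeze_band_hz: tuple[float, float] = (3.0, 8.0)
    locomotor_band_hz: tuple[float, float] = (0.5, 3.0)
    fi_ratio_min: float = 2.0
    power_floor: float = 10.0
    persist: float = 0.99
    emit: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSIONS.copy())
    prior_fog: float = 0.01
    pfog_threshold: float = 0.7

    def __post_init__(self) -> None:
        self.emit = np.asarray(self.emit, dtype=float)
        if self.emit.shape != (2, 4):
            raise UsageError("emit must be a 2x4 table P(observation | state)")
        if not np.allclose(self.emit.sum(axis=1), 1.0, atol=1e-9):
            raise UsageError("emission rows must sum to 1")
        if np.any(self.emit < 0):
            raise UsageError("emission probabilities must be non-negative")
        if not 0.0 < self.persist < 1.0:
            raise UsageError("persist must lie in (0, 1)")
        if not 0.0 < self.pfog_threshold < 1.0:
            raise UsageError("pfog_threshold must lie in (0, 1)")
        if not 0.0 < self.prior_fog < 1.0:
            raise UsageError("prior_fog must lie in (0, 1)")
        for lo, hi in (self.freeze_band_hz, self.locomotor_band_hz):
            if not lo < hi:
                raise UsageError("frequency bands must be ordered low < high")


@dataclass
class ProbabilityTrace:
    """Per-sample FOG probability for one foot, on the session clock."""

    rate_hz: float
    t0_s: float
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if not np.all(np.isfinite(self.p)):
            raise UsageError("probabilities must be finite")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise UsageError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.p.size


def _require_foot(rec: ImuRecording) -> None:
    if rec.site not in FOOT_SITES:
        raise UsageError(f"expected a foot sensor, got {rec.site!r}")


def _moving_mean(x: np.ndarray, h: int) -> np.ndarray:
    """Centered moving mean with edge-truncated windows (half-width h samples)."""
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    k = np.arange(n)
    lo = np.maximum(k - h, 0)
    hi = np.minimum(k + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def zero_velocity_flags(rec: ImuRecording, cfg: DetectorConfig) -> np.ndarray:
    """True where the centered windowed RMS of gyro magnitude is below the stance floor."""
    _require_foot(rec)
    h = int(round(cfg.zv_window_s * rec.rate_hz / 2))
    if 2 * h + 1 > rec.n_samples:
        raise UsageError("zero-velocity window is longer than the recording")
    mag2 = np.einsum("ij,ij->i", rec.gyro, rec.gyro)
    rms = np.sqrt(_moving_mean(mag2, h))
    return rms < cfg.zv_rms_dps


def band_powers(
    gyro: np.ndarray, rate_hz: float, n_window: int, freeze_band, locomotor_band
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window freeze- and locomotor-band power of the angular-velocity vector.

    For each centered window (reflection-padded at the edges) the per-axis
    signal is mean-detrended and its one-sided periodogram (boxcar window,
    'spectrum' scaling, so bin values sum to the mean square in (deg/s)^2) is
    summed over the three axes; band power is the sum over bins with
    ``low <= f < high`` for the locomotor band and ``low <= f <= high`` for the
    freeze band. Axis-summed band power equals the band energy of the vector
    signal (Parseval).
    """
    n = gyro.shape[0]
    half = n_window // 2
    pad_before, pad_after = half, n_window - half - 1
    freqs = np.fft.rfftfreq(n_window, 1.0 / rate_hz)
    in_freeze = (freqs >= freeze_band[0]) & (freqs <= freeze_band[1])
    in_loco = (freqs >= locomotor_band[0]) & (freqs < locomotor_band[1])
    # one-sided 'spectrum' scaling: 2|X|^2/N^2 at interior bins (neither band
    # includes DC or Nyquist for the rates used here)
    scale = 2.0 / n_window**2
    freeze_p = np.zeros(n)
    loco_p = np.zeros(n)
    chunk = 16384
    for axis in range(3):
        xp = np.pad(gyro[:, axis], (pad_before, pad_after), mode="reflect")
        windows = np.lib.stride_tricks.sliding_window_view(xp, n_window)
        for k0 in range(0, n, chunk):
            w = windows[k0 : k0 + chunk]
            w = w - w.mean(axis=1, keepdims=True)
            pxx = np.abs(np.fft.rfft(w, axis=1)) ** 2 * scale
            freeze_p[k0 : k0 + chunk] += pxx[:, in_freeze].sum(axis=1)
            loco_p[k0 : k0 + chunk] += pxx[:, in_loco].sum(axis=1)
    return freeze_p, loco_p


def trembling_flags(rec: ImuRecording, cfg: DetectorConfig) -> np.ndarray:
    """True where freeze-band power dominates locomotor-band power.

    A sample is flagged when freeze power exceeds ``fi_ratio_min`` times the
    locomotor power AND their sum exceeds ``power_floor`` (so quiet signals are
    never called trembling).
    """
    _require_foot(rec)
    n_window = int(round(cfg.fi_window_s * rec.rate_hz))
    if n_window > rec.n_samples:
        raise UsageError("trembling window is longer than the recording")
    freeze_p, loco_p = band_powers(
        rec.gyro, rec.rate_hz, n_window, cfg.freeze_band_hz, cfg.locomotor_band_hz
    )
    return (freeze_p > cfg.fi_ratio_min * loco_p) & (freeze_p + loco_p > cfg.power_floor)


def observation_indices(zv: np.ndarray, tremble: np.ndarray) -> np.ndarray:
    """Map the flag pair to the observation alphabet (0,0)->0,(1,0)->1,(0,1)->2,(1,1)->3."""
    zv = np.asarray(zv, dtype=bool)
    tremble = np.asarray(tremble, dtype=bool)
    if zv.shape != tremble.shape:
        raise UsageError("zero-velocity and trembling flag series differ in length")
    return zv.astype(int) + 2 * tremble.astype(int)


def pfog_forward_filter(
    zv: np.ndarray,
    tremble: np.ndarray,
    cfg: DetectorConfig,
    rate_hz: float = 100.0,
    t0_s: float = 0.0,
) -> ProbabilityTrace:
    """Causal forward posterior P(FOG at sample k | observations up to k).

    Two-state hidden process with symmetric transitions (self-probability
    ``cfg.persist``), initial prior ``cfg.prior_fog``, and the 2x4 emission
    table over observation pairs. The recursion is normalized at every step.
    """
    obs = observation_indices(zv, tremble)
    like_no = cfg.emit[0][obs]
    like_fog = cfg.emit[1][obs]
    a = cfg.persist
    p = cfg.prior_fog
    out = np.empty(obs.size)
    ln = like_no.tolist()
    lf = like_fog.tolist()
    for k in range(obs.size):
        # the prior applies to S_1 directly; transitions only between samples
        pred = p if k == 0 else p * a + (1.0 - p) * (1.0 - a)
        num = pred * lf[k]
        den = num + (1.0 - pred) * ln[k]
        p = num / den
        out[k] = p
    return ProbabilityTrace(rate_hz=rate_hz, t0_s=t0_s, p=out)


def detect_foot(rec: ImuRecording, cfg: DetectorConfig) -> ProbabilityTrace:
    """Full single-foot detector: flags then forward filter."""
    zv = zero_velocity_flags(rec, cfg)
    tr = trembling_flags(rec, cfg)
    return pfog_forward_filter(zv, tr, cfg, rate_hz=rec.rate_hz, t0_s=rec.t0_s)


def combine_feet(
    left: ProbabilityTrace, right: ProbabilityTrace, threshold: float
) -> np.ndarray:
    """FOG flag per sample: pFOG of *either* foot strictly above the threshold."""
    if len(left) != len(right):
        raise UsageError("foot probability traces differ in length")
    if abs(left.rate_hz - right.rate_hz) > 1e-9 or abs(left.t0_s - right.t0_s) > 1e-9:
        raise UsageError("foot probability traces are not on a common clock")
    return (left.p > threshold) | (right.p > threshold)
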