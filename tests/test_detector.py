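"""Two-stage detector: flag extraction, forward probability filter, foot combination."""

from itertools import product

import numpy as np
import pytest
from scipy import signal as sps

from fogatsf import (
    DetectorConfig,
    ProbabilityTrace,
    UsageError,
    combine_feet,
    pfog_forward_filter,
    trembling_flags,
    zero_velocity_flags,
)
from fogatsf.detect import band_powers, observation_indices
from .conftest import make_recording


def forward_oracle(obs, emit, persist, prior):
    """Exhaustive path-enumeration forward posterior P(S_k = FOG | o_1..k)."""
    out = []
    for k in range(1, len(obs) + 1):
        num = den = 0.0
        for path in product((0, 1), repeat=k):
            p = prior if path[0] == 1 else 1.0 - prior
            p *= emit[path[0]][obs[0]]
            for i in range(1, k):
                p *= persist if path[i] == path[i - 1] else 1.0 - persist
                p *= emit[path[i]][obs[i]]
            den += p
            if path[-1] == 1:
                num += p
        out.append(num / den)
    return np.array(out)


class TestZeroVelocityFlags:
    def test_quiet_foot_all_true(self):
        rec = make_recording(np.zeros((200, 3)))
        assert zero_velocity_flags(rec, DetectorConfig()).all()

    def test_fast_foot_all_false(self):
        g = np.zeros((200, 3))
        g[:, 0] = 100.0
        rec = make_recording(g)
        assert not zero_velocity_flags(rec, DetectorConfig()).any()

    def test_matches_loop_oracle(self, rng):
        cfg = DetectorConfig()
        g = rng.normal(0, 15, (200, 3))
        rec = make_recording(g)
        flags = zero_velocity_flags(rec, cfg)
        mag2 = (g**2).sum(axis=1)
        h = int(round(cfg.zv_window_s * 100 / 2))
        for k in range(200):
            lo, hi = max(0, k - h), min(199, k + h)
            rms = np.sqrt(np.mean(mag2[lo : hi + 1]))
            assert flags[k] == (rms < cfg.zv_rms_dps)

    def test_window_longer_than_recording(self):
        rec = make_recording(np.zeros((10, 3)))
        with pytest.raises(UsageError):
            zero_velocity_flags(rec, DetectorConfig(zv_window_s=1.0))

    def test_hip_site_rejected(self):
        rec = make_recording(np.zeros((200, 3)), site="left_hip")
        with pytest.raises(UsageError):
            zero_velocity_flags(rec, DetectorConfig())


class TestTremblingFlags:
    def test_freeze_band_oscillation_flagged(self):
        t = np.arange(500) / 100.0
        rec = make_recording(30.0 * np.sin(2 * np.pi * 5.0 * t))
        flags = trembling_flags(rec, DetectorConfig())
        assert flags[150:350].all()  # window interior

    def test_stepping_band_oscillation_not_flagged(self):
        t = np.arange(500) / 100.0
        rec = make_recording(30.0 * np.sin(2 * np.pi * 1.0 * t))
        assert not trembling_flags(rec, DetectorConfig()).any()

    def test_quiet_signal_below_power_floor(self):
        rec = make_recording(np.zeros((500, 3)))
        assert not trembling_flags(rec, DetectorConfig()).any()

    def test_band_powers_match_scipy_periodogram(self, rng):
        """Sliding band powers equal a per-window scipy periodogram computation."""
        cfg = DetectorConfig()
        rate, n_w = 100.0, 200
        g = rng.normal(0, 20, (300, 3))
        freeze, loco = band_powers(g, rate, n_w, cfg.freeze_band_hz, cfg.locomotor_band_hz)
        half = n_w // 2
        padded = np.pad(g, ((half, n_w - half - 1), (0, 0)), mode="reflect")
        for k in [0, 1, 77, 150, 299]:
            f_exp = l_exp = 0.0
            for axis in range(3):
                freqs, pxx = sps.periodogram(
                    padded[k : k + n_w, axis], fs=rate, window="boxcar",
                    detrend="constant", scaling="spectrum",
                )
                f_exp += pxx[(freqs >= 3.0) & (freqs <= 8.0)].sum()
                l_exp += pxx[(freqs >= 0.5) & (freqs < 3.0)].sum()
            assert freeze[k] == pytest.approx(f_exp, rel=1e-9)
            assert loco[k] == pytest.approx(l_exp, rel=1e-9)


class TestForwardFilter:
    def test_uninformative_likelihood_converges_to_half(self):
        cfg = DetectorConfig(emit=np.full((2, 4), 0.25))
        zv = np.zeros(1500, dtype=bool)
        trace = pfog_forward_filter(zv, zv, cfg)
        assert abs(trace.p[-1] - 0.5) < 1e-6

    def test_three_samples_match_hand_enumeration(self):
        emit = np.array([[0.4, 0.3, 0.2, 0.1], [0.1, 0.2, 0.3, 0.4]])
        cfg = DetectorConfig(emit=emit, persist=0.9, prior_fog=0.2)
        zv = np.array([True, False, True])
        tr = np.array([True, True, False])
        trace = pfog_forward_filter(zv, tr, cfg)
        obs = observation_indices(zv, tr)
        np.testing.assert_allclose(trace.p, forward_oracle(obs, emit, 0.9, 0.2), atol=1e-12)

    def test_strong_fog_evidence_saturates(self):
        emit = np.array([[0.45, 0.45, 0.05, 0.05], [0.05, 0.05, 0.45, 0.45]])
        cfg = DetectorConfig(emit=emit)  # observation (0,1): likelihood ratio 9:1
        zv = np.zeros(500, dtype=bool)
        tr = np.ones(500, dtype=bool)
        trace = pfog_forward_filter(zv, tr, cfg)
        assert trace.p[-1] > 0.99

    def test_matches_enumeration_on_random_strings(self, rng):
        cfg = DetectorConfig()
        for _ in range(20):
            zv = rng.random(6) < 0.5
            tr = rng.random(6) < 0.5
            trace = pfog_forward_filter(zv, tr, cfg)
            expected = forward_oracle(
                observation_indices(zv, tr), cfg.emit, cfg.persist, cfg.prior_fog
            )
            np.testing.assert_allclose(trace.p, expected, atol=1e-12)

    def test_probabilities_stay_in_unit_interval(self, rng):
        cfg = DetectorConfig()
        zv = rng.random(5000) < 0.3
        tr = rng.random(5000) < 0.3
        trace = pfog_forward_filter(zv, tr, cfg)
        assert np.all((trace.p >= 0) & (trace.p <= 1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(UsageError):
            pfog_forward_filter(np.zeros(5, bool), np.zeros(4, bool), DetectorConfig())


class TestDetectorRecall:
    def test_trembling_segments_are_mostly_covered(self):
        """Injected trembling freezes >= 3 s are covered by supra-threshold pFOG
        on >= 80% of their samples, pooled across episodes (fixed seed). The 2 s
        spectral window costs a few hundred ms at episode onset, so the bound is
        asserted on the pooled coverage."""
        import fogatsf
        from fogatsf.simulate import Segment, SessionPlan, SubjectProfile, simulate_session

        prof = SubjectProfile("sev", severity=1.0)
        plan = SessionPlan([Segment("walk", "walk_task", 600.0)])
        sess = simulate_session(prof, plan, 3)
        cfg = DetectorConfig()
        tl = fogatsf.detect_foot(sess.left_foot, cfg)
        tr = fogatsf.detect_foot(sess.right_foot, cfg)
        flags = combine_feet(tl, tr, cfg.pfog_threshold)
        covered = total = 0
        n_long = 0
        for a, b, kind in sess.episodes:
            if kind == "trembling" and b - a >= 3.0:
                i0, i1 = int(round(a * 100)), int(round(b * 100))
                covered += int(flags[i0:i1].sum())
                total += i1 - i0
                n_long += 1
        assert n_long >= 3, "expected several long trembling episodes at severity 1"
        assert covered / total >= 0.80


class TestCombineFeet:
    def _trace(self, p):
        return ProbabilityTrace(rate_hz=100.0, t0_s=0.0, p=np.asarray(p))

    def test_either_foot_above_threshold(self):
        out = combine_feet(self._trace([0.8, 0.0]), self._trace([0.1, 0.0]), 0.7)
        np.testing.assert_array_equal(out, [True, False])

    def test_exact_threshold_is_not_fog(self):
        out = combine_feet(self._trace([0.7]), self._trace([0.7]), 0.7)
        assert not out[0]

    def test_symmetric_in_feet(self, rng):
        a, b = self._trace(rng.random(100)), self._trace(rng.random(100))
        np.testing.assert_array_equal(combine_feet(a, b, 0.7), combine_feet(b, a, 0.7))

    def test_clock_mismatch_rejected(self):
        left = ProbabilityTrace(rate_hz=100.0, t0_s=0.0, p=np.zeros(5))
        right = ProbabilityTrace(rate_hz=100.0, t0_s=1.0, p=np.zeros(5))
        with pytest.raises(UsageError):
            combine_feet(left, right, 0.7)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(UsageError):
            ProbabilityTrace(rate_hz=100.0, t0_s=0.0, p=np.array([1.2]))
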