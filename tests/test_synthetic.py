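"""Synthetic cohort generator: plans, signals, episode process, rater emulation."""

import numpy as np
import pytest
from scipy import signal as sps

from fogatsf import (
    AnnotationTrack,
    Interval,
    compute_activity_mask,
    default_plans,
    emulate_rater,
    simulate_cohort,
    simulate_session,
)
from fogatsf.simulate import (
    Segment,
    SessionPlan,
    SubjectProfile,
    cohort_severities,
    draw_episodes,
)


@pytest.fixture(scope="module")
def severe_profile():
    return SubjectProfile("sev1", severity=1.0)


class TestPlans:
    def test_visit_plan_structure(self):
        plans = default_plans()
        visit = plans["visit"]
        assert len(visit.segments) == 7
        sitting = [s for s in visit.segments if s.name == "sitting"]
        assert sitting[0].duration_s == 600.0  # protocol: at least ten minutes seated
        assert visit.total_duration_s == 3 * 120 + 3 * 180 + 600

    def test_home_plan_is_three_identical_days(self):
        home = default_plans()["home"]
        day_total = sum(s.duration_s for s in home.segments if s.name.startswith("d1_"))
        assert home.total_duration_s == pytest.approx(3 * day_total)

    def test_duration_scaling(self):
        assert default_plans(0.1)["visit"].total_duration_s == pytest.approx(150.0)

    def test_duplicate_segment_names_rejected(self):
        from fogatsf.errors import UsageError

        with pytest.raises(UsageError):
            SessionPlan([Segment("a", "walk_task", 10), Segment("a", "sitting", 10)])


class TestEpisodeProcess:
    def test_zero_severity_draws_nothing(self):
        rng = np.random.default_rng(0)
        prof = SubjectProfile("s", severity=0.0)
        assert draw_episodes(rng, 0.0, 600.0, prof) == []

    def test_mean_duration_recovers_generator_mean(self, severe_profile):
        rng = np.random.default_rng(42)
        durs = []
        while len(durs) < 1000:
            for a, b, _ in draw_episodes(rng, 0.0, 50_000.0, severe_profile):
                durs.append(b - a)
        assert np.mean(durs[:1000]) == pytest.approx(5.0, rel=0.05)

    def test_episode_count_matches_renewal_expectation(self, severe_profile):
        """Arrivals are Poisson but suspended during episodes, so the long-run
        count follows the renewal rate T / (1/lambda + mean duration)."""
        lam = severe_profile.fog_rate_per_min / 60.0
        T = 600.0
        counts = [
            len(draw_episodes(np.random.default_rng(s), 0.0, T, severe_profile))
            for s in range(200)
        ]
        expected = T / (1.0 / lam + severe_profile.episode_mean_s)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 0.5  # +0.5 renewal edge bias

    def test_trembling_fraction(self, severe_profile):
        rng = np.random.default_rng(7)
        eps = draw_episodes(rng, 0.0, 50_000.0, severe_profile)
        frac = np.mean([k == "trembling" for _, _, k in eps])
        assert frac == pytest.approx(0.7, abs=0.05)


@pytest.fixture(scope="module")
def session(severe_profile):
    plan = SessionPlan(
        [
            Segment("walk", "walk_task", 120.0),
            Segment("sitting", "sitting", 600.0),
            Segment("walk2", "walk_task", 120.0),
        ]
    )
    return simulate_session(severe_profile, plan, 11), plan


class TestSimulateSession:
    def test_zero_severity_has_no_fog(self):
        prof = SubjectProfile("s0", severity=0.0)
        plan = SessionPlan([Segment("walk", "walk_task", 60.0)])
        sess = simulate_session(prof, plan, 0)
        assert sess.truth.fog_intervals() == []

    def test_deterministic_for_fixed_seed(self, severe_profile):
        plan = SessionPlan([Segment("walk", "walk_task", 30.0)])
        a = simulate_session(severe_profile, plan, 5)
        b = simulate_session(severe_profile, plan, 5)
        np.testing.assert_array_equal(a.left_foot.gyro, b.left_foot.gyro)
        np.testing.assert_array_equal(a.left_hip.accel, b.left_hip.accel)
        assert a.episodes == b.episodes

    def test_truth_never_overlaps_and_avoids_sitting(self, session):
        sess, plan = session
        ivs = sess.truth.fog_intervals()
        for a, b in zip(ivs, ivs[1:]):
            assert b.start_s >= a.end_s
        for iv in ivs:  # sitting spans 120..720
            assert iv.end_s <= 120.0 or iv.start_s >= 720.0

    def test_sitting_mostly_sedentary_despite_leg_bounce(self, session):
        sess, _ = session
        mask = compute_activity_mask(sess.left_hip)
        sitting = mask.flags[12000:72000]
        assert np.mean(~sitting) >= 0.95

    def test_walking_time_is_active(self, session):
        sess, _ = session
        mask = compute_activity_mask(sess.left_hip)
        assert mask.flags[1000:11000].mean() > 0.99

    def test_spectral_peaks_by_segment_kind(self, severe_profile):
        plan = SessionPlan([Segment("walk", "walk_task", 300.0)])
        sess = simulate_session(severe_profile, plan, 11)
        trembles = [(a, b) for a, b, k in sess.episodes if k == "trembling" and b - a > 3]
        assert trembles, "expected at least one long trembling episode"
        a, b = trembles[0]
        seg = sess.left_foot.gyro[int(a * 100) + 50 : int(b * 100) - 50, 1]
        f, pxx = sps.periodogram(seg, fs=100.0, detrend="constant")
        peak = f[np.argmax(pxx)]
        assert 3.0 <= peak <= 8.0
        # a clean walking stretch before the first episode
        first = min(x for x, _, _ in sess.episodes)
        if first > 8.0:
            walk = sess.left_foot.gyro[200 : int(first * 100) - 200, 1]
            f, pxx = sps.periodogram(walk, fs=100.0, detrend="constant")
            peak = f[np.argmax(pxx)]
            assert 0.5 <= peak < 3.0


class TestEmulateRater:
    def _truth(self, ivs):
        return AnnotationTrack("s", [Interval(a, b, "fog") for a, b in ivs])

    def test_no_jitter_no_floor_is_identity(self):
        truth = self._truth([(1.0, 4.0), (10.0, 12.5)])
        out = emulate_rater(truth, jitter_sd_s=0.0, min_episode_s=0.0, seed=3)
        assert [(iv.start_s, iv.end_s) for iv in out.fog_intervals()] == [
            (1.0, 4.0), (10.0, 12.5)]

    def test_short_episode_dropped(self):
        out = emulate_rater(self._truth([(1.0, 1.3)]), jitter_sd_s=0.0,
                            min_episode_s=0.5, seed=0)
        assert len(out.fog_intervals()) == 0

    def test_boundaries_match_replayed_noise_stream(self):
        truth = self._truth([(5.0, 11.0), (20.0, 27.0)])
        out = emulate_rater(truth, jitter_sd_s=0.2, min_episode_s=0.5, seed=9)
        rng = np.random.default_rng(np.random.SeedSequence(9))
        expected = []
        for iv in truth.fog_intervals():
            ds, de = rng.normal(0.0, 0.2, 2)
            expected.append((max(0.0, iv.start_s + ds), iv.end_s + de))
        got = [(iv.start_s, iv.end_s) for iv in out.fog_intervals()]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_jitter_keeps_start_before_end(self):
        truth = self._truth([(0.1, 0.8)])
        for seed in range(30):
            out = emulate_rater(truth, jitter_sd_s=1.0, min_episode_s=0.0, seed=seed)
            for iv in out.fog_intervals():
                assert iv.start_s < iv.end_s and iv.start_s >= 0.0


class TestCohort:
    def test_severities_include_two_zero_subjects(self):
        sev = cohort_severities(19)
        assert len(sev) == 19
        assert (sev[:2] == 0).all() and sev.max() == 1.0
        assert np.all(np.diff(sev[2:]) > 0)

    def test_file_tree_and_determinism(self, tmp_path):
        plans = default_plans(duration_scale=0.02)
        t1 = simulate_cohort(n=3, seed=4, out_dir=tmp_path / "a", plans=plans,
                             include_home=False)
        t2 = simulate_cohort(n=3, seed=4, out_dir=tmp_path / "b", plans=plans,
                             include_home=False)
        assert (t1 == t2).all().all()
        for sid in t1.index:
            vdir = tmp_path / "a" / sid / "visit"
            for name in ("left_foot", "right_foot", "left_hip", "truth", "rater", "tasks"):
                assert (vdir / f"{name}.csv").exists()
        assert (tmp_path / "a" / "cohort_truth.csv").exists()
        # the two severity-0 subjects carry no FOG
        assert t1["true_fog_visit_s"].iloc[:2].eq(0).all()
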