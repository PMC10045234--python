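"""Simulate one subject's in-person visit and inspect the ground truth.

Builds a moderately severe subject, generates the three sensor streams for the
default visit plan (clinic gait tasks, IADL tasks, a 10-minute sitting task)
and prints the injected FOG episodes. Severity drives the episode rate; the
truth track is exact, so it can anchor any downstream validation.
"""

from fogatsf import default_plans, simulate_session
from fogatsf.simulate import SubjectProfile

profile = SubjectProfile("demo", severity=0.8)
plan = default_plans()["visit"]
session = simulate_session(profile, plan, seed=42)

print(f"subject {profile.subject_id}: severity {profile.severity}, "
      f"{profile.fog_rate_per_min:.2f} episodes per active minute")
print(f"visit duration: {plan.total_duration_s / 60:.0f} min, "
      f"{session.left_foot.n_samples} samples per sensor at "
      f"{session.left_foot.rate_hz:g} Hz")
print(f"\ninjected FOG episodes ({len(session.episodes)}):")
for start, end, kind in session.episodes:
    print(f"  {start:7.1f} - {end:7.1f} s  {end - start:5.1f} s  {kind}")
total = session.truth.total_fog_s()
print(f"\ntotal FOG time: {total:.1f} s "
      f"({100 * total / plan.total_duration_s:.1f}% of the session)")
# Trembling episodes oscillate the feet at 5 Hz; akinetic episodes still the
# feet while the hip keeps moving, which is what the detector must separate
# from ordinary stepping and from sitting.
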