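# Methods

This note documents the models, conventions and numerical choices behind
`fogatsf`, and what the synthetic validation does and does not establish.

## Signal model and I/O

An `ImuRecording` is a uniformly sampled tri-axial gyroscope (deg/s) and
optional accelerometer (g) stream for one site (left/right foot, left hip);
sample *k* sits at `t0_s + k / rate_hz`. Files are plain CSV with sidecar
comment lines for subject, site and rate. Commercial sensors in this setting
record at 100 or 128 Hz; 128 Hz streams are brought to the common 100 Hz
analysis rate by a Hann-windowed sinc interpolator:

* kernel half-width 64 source samples, reflection padding at the edges,
  tap weights normalized to unit sum (constants are preserved exactly,
  sub-10 Hz sine amplitudes to well within 1%);
* output timestamps anchored at `t0 + k / target_rate`, covering the input
  span with any trailing partial sample dropped
  (`n_out = floor((n-1)·ratio) + 1`).

The accelerometer is carried through I/O and resampling but unused by the
detector: the analysis is gyro-driven.

## Activity mask (sedentary exclusion)

Total hip angular speed is defined as `|gx| + |gy| + |gz|`. It is smoothed by
a **centered 20 s moving average** with windows truncated (shrunk) at the
recording edges — no data is invented at session boundaries — and compared
**strictly** against 1 deg/s: samples at exactly the threshold are sedentary.
An alternative per-axis reading ("any plane above threshold") is available as
`per_axis=True` but off by default; the summed form is the stated definition
of total angular speed. The mask is computed per contiguous recording.

This rule is what makes %ATSF a *percent of active time*: a subject sitting
and bouncing a leg keeps the hip still and is excluded even though a foot
sensor shows 2 Hz motion.

## FOG detector (stand-in)

The published pFOG detector's internals (detection / navigation / filtering
modules) are not reconstructible from the available description, so the
package implements an explicitly labeled stand-in that preserves the
documented structure — two-stage event extraction feeding a probability
filter, thresholded at 0.7 for either foot. All parameters live in
`DetectorConfig`:

| parameter | default | meaning |
|---|---|---|
| `zv_window_s` / `zv_rms_dps` | 0.25 s / 10 deg/s | stance-stillness RMS window and floor |
| `fi_window_s` | 2.0 s | spectral window for trembling detection |
| `freeze_band_hz` / `locomotor_band_hz` | 3–8 / 0.5–3 Hz | freeze-index band convention of the wearable-FOG literature |
| `fi_ratio_min` / `power_floor` | 2.0 / 10 (deg/s)² | freeze-to-locomotor dominance and minimum energy |
| `persist` | 0.99 | hidden-state self-transition per sample (≈ 1 s dwell at 100 Hz scale) |
| `emit` | see below | P(observation pair \| state) |
| `prior_fog` | 0.01 | FOG is rare at session start |
| `pfog_threshold` | 0.7 | supra-threshold level defining FOG |

Band power is computed as the **axis-summed** per-window periodogram power
(boxcar window, per-window mean removal, one-sided 'spectrum' scaling). By
Parseval this equals the band energy of the angular-velocity vector; computing
a periodogram of the Euclidean magnitude instead would rectify single-axis
oscillations to twice their frequency and push 3–8 Hz trembling out of its own
band. The locomotor band is half-open (`0.5 ≤ f < 3`), the freeze band closed
(`3 ≤ f ≤ 8`), so the shared 3 Hz bin counts as freeze.

The emission table over observation pairs (zv, tremble) =
(0,0), (1,0), (0,1), (1,1):

```
P(o | noFOG) = 0.60, 0.25, 0.10, 0.05
P(o | FOG)   = 0.10, 0.20, 0.20, 0.50
```

chosen so simultaneous stillness-plus-trembling strongly favors FOG, while
plain stillness (ordinary stance) slightly favors noFOG. The forward recursion
is causal (no smoothing), normalized at every step; the prior applies to the
first sample directly, transitions only between samples.

Consequences worth knowing: trembling freezes are detected with a few hundred
milliseconds of onset latency (the 2 s spectral window must clear the last
pre-freeze step), and **akinetic freezes are largely invisible** — sustained
stillness under an active hip resembles stance, and the (1,0) observation has
likelihood ratio 0.8. The sensor therefore undercounts %ATSF relative to the
rater, and sensitivity is the diagnostic to watch; both behaviors match the
qualitative pattern reported for sensor-vs-video comparisons in this setting.

## Events, scoring, statistics

Events are half-open `[start, end)`; a sample belongs to an interval iff
`start ≤ t_k < end`, applied identically to detector events and rater
annotations. Detector events separated by **strictly less than 2 s** are merged
(transitively; a gap of exactly 2 s survives); rater episodes are never merged.
Merging happens on the full timeline *before* active-time restriction, since
sedentary exclusion is an analysis-time filter.

Accuracy, sensitivity, specificity and %ATSF are computed over active samples
only; for the visit, over active samples *inside task intervals* (inter-task
transition time is excluded). Undefined metrics (no active samples in a task,
no reference FOG) are reported as missing, never as 0, to avoid biasing cohort
means. Mean episode duration is computed from the rater's episodes — episode
duration is an expert-review quantity in this design. Home %ATSF pools all
home recordings after sedentary exclusion.

Cohort association uses Spearman's ρ as Pearson correlation of average-ranked
values (ties get mean ranks), with pairwise-complete deletion for missing
cells; matrix cells whose correlation is undefined propagate as missing.
Shapiro–Wilk (via scipy) records the normality gate that motivates the
nonparametric choice; ρ is reported without p-values by default (the
t-approximation is available via `spearman_test`).

## Synthetic cohort generator

The generator's job is to exercise every pipeline branch under controlled
truth, not biomechanical fidelity. Signals are piecewise-stationary
oscillators plus Gaussian sensor noise:

* **walking / IADL / home movement**: half-sine swing pulses (0.3 s, 200 deg/s)
  per foot at a 1.8 steps/s cadence (feet in anti-phase), hip angular rate
  10 ± 6 deg/s;
* **trembling FOG**: 5 Hz, 25 deg/s foot oscillation, both feet, hip active;
* **akinetic FOG**: residual foot motion < 1 deg/s, hip active;
* **sitting**: hip ≈ 0.2 deg/s, occasional one-foot 2 Hz / 20 deg/s leg-bounce
  bursts (Poisson, 2/min, 2–5 s).

Episodes arrive as a Poisson process during movement segments at
1.5 × severity per active minute, with log-normal durations of mean 5 s
(shape 0.5); arrivals are suspended during episodes, so counts follow the
renewal rate T/(1/λ + 5 s). Gyro noise is σ = 0.2 deg/s per axis — a typical
MEMS noise floor, and necessarily below the sedentary threshold: the rectified
sum of three axes of N(0, σ²) noise has mean 3σ√(2/π), which must stay under
1 deg/s for quiet sitting to be classified sedentary at all. Accelerometer
noise is 0.02 g around a 1 g baseline.

The default visit plan is three 120 s clinic gait tasks, three 180 s IADL
tasks and a 600 s sitting task (≈ 25 min); home wear is three desk-scale days
of ~30 min each (durations scale with one factor). The cohort default is 19
subjects with severities spaced over [0, 1] including two FOG-free subjects.
The questionnaire analog is `clamp(round(28·(0.3·severity + 0.7·U)))` —
noise-dominated by design, so the cohort analysis can demonstrate the
dissociation between self-report and objective measures. The rater emulation
jitters episode boundaries by N(0, 0.2 s²) and drops episodes shorter than
0.5 s. All randomness derives from one integer seed via counter-style
`SeedSequence([seed, subject, stream])` keys; every artifact is independently
replayable.

**What passing tests show — and don't.** The synthetic signals are clean
oscillators: real gait has variable cadence, turning transients, freeze
phenotypes that blend trembling and akinesia, and sensor artifacts (donning
errors, clipping). Detection accuracy and correlation figures obtained on this
cohort validate the pipeline's mechanics and conventions, not the stand-in
detector's clinical performance.

## Numerical choices and degenerate inputs

* Moving-window primitives use cumulative sums (O(n)), edge-truncated; the
  spectral stage uses strided windows with chunked FFTs (memory-bounded).
* Interval→sample mapping guards float boundaries with a 1e-9 sample-unit
  epsilon, so `0.02·100` landing at `2.0000000000000004` still excludes
  sample 2 under the half-open rule.
* The forward recursion is normalized every step; posteriors are exactly in
  [0, 1] by construction.
* Degenerate inputs raise typed errors: upsampling requests, windows longer
  than the recording, empty event lists, zero active samples, constant vectors
  in Shapiro–Wilk or rank correlation. A FOG-free subject is a *valid* row
  (accuracy 100%, %ATSF 0), not an error.

## Validation scale

The acceptance computation simulates the 19-subject cohort at the full visit
scale (25 min per subject, ≈ 150,000 samples per sensor) and completes in
about half a minute; unit and property suites run on seconds-long traces with
brute-force loop, enumeration and fixpoint oracles, plus an exhaustive
forward-filter check over all 1024 length-5 observation strings.
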