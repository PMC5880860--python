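# Methods

This note records the model assumptions, parameter choices, numerical
details and known limitations of `gazeparse`.

## Signal model and units

A recording is a per-trial time series of binocular gaze positions in
screen pixels (origin top-left, y downward), with per-sample eye-to-screen
distance in mm.  Angles use the full two-point subtense formula
`2·atan(d_mm / (2·distance))` with per-axis mm-per-pixel factors, so
anisotropic pixels are handled and no small-angle approximation is made.
Missing distance falls back to the trial median, then to the configured
default: viewing distance drifts on a scale of seconds, far slower than
gaze, so a per-trial fallback is safe.

Speed is the central difference — the Euclidean displacement between the
preceding and succeeding sample over the elapsed time — with no
pre-filtering; all noise handling is deferred to the adaptive threshold.  A
speed is attributed to a sample only when the sample and both neighbours
are measured; trial-boundary samples have no speed.

## The adaptive velocity threshold

Local speed maxima (samples strictly faster than both valid neighbours) are
collected per trial.  Fixational noise produces a dense cluster of maxima
whose scale is set by the noise SD and the sampling rate; saccadic peaks
form a sparse tail.  For candidate speeds v the observed exceedance
S_obs(v) = #{maxima > v} is compared with the uniform-null expectation
S_null(v) = n·(max − v)/(max − min); the gap statistic is their difference
as fractions, (S_null − S_obs)/n.  It is maximal just above the dense
cluster — the point where observed maxima start falling short of the
uniform expectation fastest.

Numerical choices:

* **Candidate grid.** 512 evenly spaced *quantiles* of the maxima
  (inverted-CDF, i.e. observed speeds at evenly spaced ranks).  Spacing
  candidates evenly in speed instead concentrates them in the sparse tail,
  where a handful of saccadic peak speeds carve secondary gap modes that no
  smoothing bandwidth removes; on the quantile grid the tail holds few
  candidates and the curve is reliably unimodal.  Inverted-CDF quantiles
  also make the curve exactly invariant under duplication of the sample.
* **Gap scale.** The difference is taken on the plain count scale
  (normalised by n), not as a log-ratio.  A log-ratio is maximised where
  the *ratio* of null to observed counts is extreme — deep in the tail,
  between saccade-peak clusters, where both counts are tiny.  On clean
  trials this misplaces the threshold by hundreds of deg/s and makes it
  unstable under single-dropout perturbations; the linear difference lands
  at the noise-cluster edge in every regime.
* **Smoothing.** Locally weighted quadratic regression with tricube
  weights (batched 3×3 normal equations with a 1e-12 ridge), at spans
  0.10, 0.15, …, 1.00 of the grid; the first span whose fit has exactly one
  strict interior maximum wins.  Ties at the maximum take the smallest
  candidate speed (conservative: more saccades detected).
* **Validity.** A trial is inestimable (no events, flagged diagnostic) when
  it has fewer than 10 local maxima, a degenerate speed range, or no span
  yields a unimodal curve (~2% of clean simulated trials, where saccadic
  peak speeds happen to cluster into two groups).

The same machinery applied to log initial-fixation durations yields a
data-driven duration threshold (`mould` method only).  It needs a lot of
data to be meaningful: below 50 durations (default, config-exposed) it
falls back to the fixed 100-ms threshold.  With a unimodal duration sample
the estimated split point can land *inside* the distribution and discard
real fixations, which is why the primary method uses the fixed threshold.

## Post-processing

Missing runs shorter than 250 ms are linearly interpolated iff the
straight-line speed between the flanking samples does not exceed the
velocity threshold (a saccade takes ~200 ms to program, so longer losses
may hide one; the velocity guard catches position jumps across shorter
ones).  A run's duration is its sample count times the nominal period.

Classification uses "below threshold ⇒ fixation candidate" with the
boundary sample counted saccadic (the rule is *below*).  Event timing is
half-open: an event starts at its first sample's timestamp and ends one
nominal period after its last, so durations tile the trial exactly.

Successive fixations merge when their convex hulls intersect (fixations
with fewer than three distinct points use a disc of radius one median
intra-fixation RMS); everything between them is absorbed, and merging
repeats to a fixed point.  Finally fixations shorter than 100 ms are
unclassified (kept iff duration ≥ threshold; their samples rejoin no
event).

## Comparison parsers

`mould` = adaptive velocity + data-driven duration threshold, no
interpolation and no spatial merge; `mouldDur` = same with the fixed 100-ms
duration threshold; `velocity` = fixed 35 deg/s + 100 ms; `dispersion` =
running-centroid I-DT: a fixation grows while each new sample stays within
0.9° of the running centroid, the breaking sample seeds the next window,
missing samples end the window, and only fixations are classified.  The
split/unmatched comparison (`compare_parsings`) counts, for each fixation
of one parse, the fixations of the other parse contained in its span
(tolerance one sample period; ≥2 ⇒ split, no overlap at all ⇒ unmatched).

## Data-quality measures

Robustness is the mean length (ms) of maximal contiguous valid-sample runs;
precision is the mean over consecutive 100-ms windows (aligned to trial
start, ≥2 valid samples) of the mean Euclidean deviation of raw samples
from the window mean.  Both are computed on pre-interpolation data, so
interpolation cannot launder quality.  Within precision, the deviation is
Euclidean (not per-axis), an isolated choice.  Per-event statistics: sdPOG
= √(var x + var y) in px (n−1 estimator); within-fixation RMS of
successive displacements in degrees (precision convention); saccade
amplitude = first-to-last-sample subtense in degrees.

## The simulator

The generator emulates the two quality axes the parser must absorb —
precision (additive noise) and robustness (missing-data flicker) — around
a piecewise-stationary scanpath:

* fixation durations lognormal, median 700 ms, log-SD 0.3
  (free-viewing-like; negligible mass below the 100-ms threshold, so the
  true event count is recoverable by contract);
* fixation centres uniform over the stimulus with a 5° minimum saccade
  amplitude — a clean-regime choice: a 2° saccade's raised-cosine peak
  (~157 deg/s) sits below the adapted threshold at 0.15° noise and is not
  a recoverable event at 500 Hz;
* saccade duration = 2.2 ms/deg · amplitude + 21 ms with a raised-cosine
  speed profile (textbook main-sequence phenomenology, config-exposed);
* trials tile exactly: the last fixation stretches to the trial end, so
  ground truth never contains a fragment whose classification is ambiguous
  at the duration threshold;
* `noise_sd_deg` is the pooled 2-D SD (each axis gets sd/√2), the same
  scale as the sdPOG statistic the package reports;
* flicker is a two-state process with geometric run lengths, independent
  per eye so binocular filling is genuinely exercised; the right eye is
  the left plus a fixed 5-px offset, before noise.

Each trial draws its event plan and its noise from separate substreams, so
the true event sequence is identical across sampling rates and noise
settings — the property that makes quality-decorrelation experiments
meaningful (the true duration law is independent of the quality knobs by
construction).

What the simulator does **not** model: smooth pursuit, drift and
microsaccades within fixations, saccadic curvature, pupil signals,
head-geometry changes, calibration bias, or temporally correlated noise.
Passing the validation experiments therefore shows the pipeline recovers
piecewise-stationary scanpaths under realistic noise/flicker, not that it
handles pursuit-rich or drift-heavy data.

## Validation experiment sizes

`scripts/acceptance.py` and `tests/test_acceptance.py` run: 100
single-trial recordings (500 Hz, 8 s, ~10 fixations, 0.15° noise) for
clean-regime recovery; 20 seeds × noise ∈ {0.05, 0.1, 0.2, 0.4, 0.8}° for
threshold adaptivity; 100 paired clean/dropout recordings at 0.03° noise
(EyeLink-grade, so the 35 deg/s fixed baseline is sensible) with three
80–200-ms in-fixation dropouts for robustness; and 60-participant cohorts
(3 × 6-s trials each, noise ~ U(0.05, 1.0)°, missing fraction ~ U(0, 0.3))
for quality decorrelation.

## Known limitations

* The uniform-null gap construction is one operationalisation of a method
  described only qualitatively in the literature; it is isolated behind
  `gazeparse.threshold.gap_curve` so it can be swapped.
* Event boundaries carry a systematic bias of roughly a quarter of a
  saccade's rise time (the threshold is crossed after saccade onset and
  before offset), ~5–10 ms at 500 Hz in the clean regime.
* The shape of the step-5 polygon (convex hull) is a choice; a bounding
  box or dispersion ellipse would merge slightly differently.
* Trials whose saccadic peak speeds split into well-separated clusters can
  defeat the unimodality search and are reported as inestimable rather
  than guessed at.
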