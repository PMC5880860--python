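# gazeparse

Adaptive, data-driven parsing of raw eye-tracking samples into fixations and
saccades.

## The problem

Eye-tracking analyses start by segmenting the raw gaze signal into
**fixations** (gaze held still, information encoded) and **saccades** (rapid
ballistic jumps).  Manufacturer algorithms do this with one fixed threshold
for everyone — e.g. a 35 deg/s velocity threshold (EyeLink) or a 0.9°
dispersion threshold (Tobii ClearView).  That breaks down when data quality
varies: noisy or flickering recordings (infants, clinical populations,
low-end trackers) cross a fixed threshold spuriously, shattering fixations
into short fragments, so measured fixation durations end up correlated with
data quality rather than with behaviour.

`gazeparse` instead estimates a **velocity threshold per trial from the data
itself** and adds robustness-aware post-processing, so one method can be
applied to every participant — from 60 Hz infant data to 500 Hz adult
reading data — while still adapting to each trial's noise level.

## The method

For each trial:

1. **Binocular merge** — left/right eyes are averaged; a missing eye is
   filled from the other.
2. **Adaptive velocity threshold** — per-sample speed (deg/s) comes from the
   central difference of successive positions.  Samples faster than both
   neighbours are *local speed maxima*; fixational jitter contributes a
   dense low-speed cluster of maxima and saccades a sparse high-speed tail.
   The exceedance count above each candidate speed v, S(v) = #{maxima > v},
   is compared with the count expected under a uniform null on the same
   range; their difference (the *gap statistic*) is smoothed by locally
   weighted quadratic regression with increasing bandwidth until it has
   exactly one maximum.  The speed at that maximum is the threshold.
3. **Gap interpolation** — missing runs shorter than 250 ms are filled
   linearly, but only if the bridging velocity across the gap stays below
   the threshold (so a saccade hidden inside the gap is never papered over).
4. **Classification** — samples below the threshold are fixation
   candidates, above it saccade candidates; runs become candidate events.
5. **Spatial merge** — successive fixations whose convex hulls overlap are
   merged (heals fixations split by noise bursts).
6. **Duration threshold** — fixations shorter than 100 ms are discarded.

Alternative parsers (`mould`, `mouldDur`, `velocity`, `dispersion`) are
included for comparison, along with the data-quality measures **robustness**
(mean contiguous valid-segment length) and **precision** (mean deviation of
the raw signal from its 100-ms-window means), and a ground-truth scanpath
simulator for validation.

## Worked example

```python
import gazeparse as gp

spec = gp.SimulationSpec(n_trials=2, noise_sd_deg=0.2, mean_valid_run_ms=800.0)
rec, truth = gp.simulate(spec, seed=7, participant_id="demo")
table, parses = gp.parse_recording(rec, gp.ParserConfig(method="gazepath"))

for tp in parses:
    print(f"trial {tp.trial}: threshold {tp.velocity_threshold:.1f} deg/s, "
          f"{sum(e.kind == 'f' for e in tp.events)} fixations "
          f"(true: {truth.fixation_count(tp.trial)})")
print(table.head(6).round(2).to_string(index=False))
```

```
trial 1: threshold 128.4 deg/s, 10 fixations (true: 10)
trial 2: threshold 125.7 deg/s, 12 fixations (true: 12)
Participant Value  Duration  Start    End  mean_x  mean_y  sdPOGsacAMP  RMS  Order  Trial
       demo     f     748.0    2.0  750.0  504.51  156.11         6.10 0.21      1      1
       demo     s      28.0  750.0  778.0  280.16  185.99         9.89  NaN      2      1
       demo     f    1114.0  778.0 1892.0   56.93  214.64         6.25 0.21      3      1
       demo     s      64.0 1892.0 1956.0  586.64  558.19        28.92  NaN      4      1
       demo     f     782.0 1956.0 2738.0 1075.71  873.88         5.50 0.19      5      1
       demo     s      42.0 2738.0 2780.0 1110.66  548.68        16.53  NaN      6      1
```

The simulated recording carries 0.2° of measurement noise and intermittent
signal loss; the threshold settles near the top of the noise cluster
(~128 deg/s at 500 Hz) and the parser recovers the true fixation count in
both trials.  In the output table, `Value` is `f`/`s`, times are ms from
trial start, `sdPOGsacAMP` holds the point-of-gaze SD in px for fixations
and the amplitude in degrees for saccades, and `RMS` is the
successive-sample RMS displacement in degrees within each fixation.

The same pipeline is available from the shell:

```sh
gazeparse simulate --seed 1 --participants 3 --out-dir raw/
gazeparse parse raw/sim*.csv --config run.yaml --method gazepath --out-dir out/
gazeparse compare out/a_events.csv out/b_events.csv
```

`run.yaml` names the columns of the raw export, the screen/stimulus
geometry and the sampling rate (see `tests/test_cli.py` for a complete
example).

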