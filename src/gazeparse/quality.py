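"""Data-quality measures and per-event statistics.

Two trial-level quality measures are reported:

* **robustness** — the mean duration of maximal contiguous runs of valid
  (non-missing, pre-interpolation) samples: high when the signal is
  uninterrupted, low when it flickers on and off;
* **precision** — the trial is cut into consecutive 100-ms windows, the
  signal is smoothed to the per-window mean, and precision is the mean over
  windows of the mean raw-to-smoothed deviation.  Low values indicate high
  precision.

Per-event statistics fill the ``sdPOGsacAMP`` and ``RMS`` output columns:
the pooled two-dimensional standard deviation of the point of gaze (px) and
the RMS of successive-sample displacements (degrees) for fixations, the
first-to-last-sample amplitude (degrees) for saccades.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import GazeEvent, Geometry
from .kinematics import px_to_deg

__all__ = ["robustness", "precision", "fixation_stats", "saccade_amplitude",
           "event_stats", "trial_quality", "quality_outcome_correlation"]


def robustness(valid_mask: np.ndarray, period_ms: float) -> float:
    """Mean length (ms) of maximal contiguous valid-sample runs; 0 if none."""
    m = np.asarray(valid_mask, dtype=bool)
    if not m.any():
        return 0.0
    padded = np.concatenate([[False], m, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    lengths = (ends - starts) * period_ms
    return float(lengths.mean())


def precision(x: np.ndarray, y: np.ndarray, time_ms: np.ndarray,
              window_ms: float = 100.0) -> float:
    """Mean raw-to-smoothed deviation (px) over 100-ms windows.

    Windows are consecutive bins aligned to the trial start; only windows
    with at least two valid samples contribute.  Returns NaN when no window
    is eligible.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t = np.asarray(time_ms, float)
    if len(t) == 0:
        return float("nan")
    bins = np.floor((t - t[0]) / window_ms).astype(int)
    scores = []
    for b in np.unique(bins):
        sel = bins == b
        xs, ys = x[sel], y[sel]
        ok = ~np.isnan(xs) & ~np.isnan(ys)
        if ok.sum() < 2:
            continue
        sx, sy = xs[ok].mean(), ys[ok].mean()
        dev = np.hypot(xs[ok] - sx, ys[ok] - sy)
        scores.append(dev.mean())
    return float(np.mean(scores)) if scores else float("nan")


def fixation_stats(event: GazeEvent, samples: pd.DataFrame,
                   geometry: Geometry):
    """Centroid (px), pooled 2-D SD of the point of gaze (px), and RMS of
    successive displacements (degrees of visual angle) for a fixation.

    sdPOG uses the n-1 variance estimator: sqrt(var(x) + var(y)).  RMS is
    NaN for single-sample fixations.
    """
    seg = samples.iloc[event.first_sample:event.last_sample + 1]
    xs = seg["x"].to_numpy(float)
    ys = seg["y"].to_numpy(float)
    dist = seg["dist"].to_numpy(float)
    ok = ~np.isnan(xs) & ~np.isnan(ys)
    xs, ys, dist = xs[ok], ys[ok], dist[ok]
    if len(xs) == 0:
        return float("nan"), float("nan"), float("nan"), float("nan")
    mean_x, mean_y = float(xs.mean()), float(ys.mean())
    if len(xs) < 2:
        return mean_x, mean_y, 0.0, float("nan")
    sdpog = float(np.sqrt(np.var(xs, ddof=1) + np.var(ys, ddof=1)))
    step_deg = px_to_deg(np.diff(xs), np.diff(ys), geometry,
                         0.5 * (dist[:-1] + dist[1:]))
    rms = float(np.sqrt(np.mean(step_deg ** 2)))
    return mean_x, mean_y, sdpog, rms


def saccade_amplitude(event: GazeEvent, samples: pd.DataFrame,
                      geometry: Geometry) -> float:
    """Amplitude (degrees) between a saccade's first and last valid sample.

    By construction path-independent: only the endpoints matter.  NaN with
    fewer than two valid samples.
    """
    seg = samples.iloc[event.first_sample:event.last_sample + 1]
    xs = seg["x"].to_numpy(float)
    ys = seg["y"].to_numpy(float)
    dist = seg["dist"].to_numpy(float)
    ok = ~np.isnan(xs) & ~np.isnan(ys)
    if ok.sum() < 2:
        return float("nan")
    i, j = np.where(ok)[0][[0, -1]]
    return float(px_to_deg(xs[j] - xs[i], ys[j] - ys[i], geometry,
                           0.5 * (dist[i] + dist[j])))


def event_stats(event: GazeEvent, samples: pd.DataFrame, geometry: Geometry
                ) -> dict:
    """Output-schema statistics for one event (fixation or saccade)."""
    if event.kind == "f":
        mean_x, mean_y, sdpog, rms = fixation_stats(event, samples, geometry)
        return {"mean_x": mean_x, "mean_y": mean_y,
                "sdPOGsacAMP": sdpog, "RMS": rms}
    seg = samples.iloc[event.first_sample:event.last_sample + 1]
    xs, ys = seg["x"].to_numpy(float), seg["y"].to_numpy(float)
    ok = ~np.isnan(xs) & ~np.isnan(ys)
    mean_x = float(xs[ok].mean()) if ok.any() else float("nan")
    mean_y = float(ys[ok].mean()) if ok.any() else float("nan")
    amp = saccade_amplitude(event, samples, geometry)
    return {"mean_x": mean_x, "mean_y": mean_y,
            "sdPOGsacAMP": amp, "RMS": float("nan")}


def trial_quality(trial: pd.DataFrame, period_ms: float,
                  window_ms: float = 100.0) -> dict:
    """Robustness and precision of one trial of (pre-interpolation) samples."""
    x = trial["x"].to_numpy(float)
    y = trial["y"].to_numpy(float)
    t = trial["time"].to_numpy(float)
    valid = ~np.isnan(x) & ~np.isnan(y)
    return {"robustness_ms": robustness(valid, period_ms),
            "precision_px": precision(x, y, t, window_ms),
            "n_valid_samples": int(valid.sum()), "n_samples": int(len(x))}


def quality_outcome_correlation(table: pd.DataFrame):
    """Pearson correlations of data quality with median fixation duration.

    ``table`` needs one row per participant with columns ``precision``,
    ``robustness`` and ``median_duration``.  Returns
    ``(r_precision, r_robustness)``; a zero-variance column yields NaN.
    Negative r(precision, duration) — noisier data, shorter fixations — is
    the signature of quality-driven spurious fixations.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 participants")
    out = []
    for col in ("precision", "robustness"):
        sub = table[[col, "median_duration"]].dropna()
        if len(sub) < 3 or sub[col].std() == 0 or sub["median_duration"].std() == 0:
            out.append(float("nan"))
        else:
            out.append(float(sstats.pearsonr(sub[col], sub["median_duration"])[0]))
    return tuple(out)
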