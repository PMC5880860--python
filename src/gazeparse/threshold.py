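"""Data-driven velocity threshold estimation.

The estimator locates, per trial, the speed that separates the dense cluster
of noise-driven local speed maxima (fixational jitter) from the sparse tail
of saccadic peaks, without any starting value:

1. collect the speeds of all local maxima of the speed profile;
2. compare the observed exceedance count above each candidate speed with the
   exceedance expected under a uniform null on the same range — their
   difference on a log scale is the gap statistic;
3. smooth the gap curve with locally weighted quadratic regression (tricube
   weights), increasing the bandwidth until the curve has exactly one
   interior maximum; the speed at that maximum is the threshold.

The same gap-statistic machinery can be applied to log initial fixation
durations to derive a data-driven duration threshold; this is unreliable on
small samples and is used only by the ``mould`` parsing method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SpeedProfile, ThresholdEstimate

__all__ = ["local_maxima", "gap_curve", "loess_quadratic",
           "smooth_until_unimodal", "estimate_threshold",
           "duration_threshold_data_driven",
           "DEFAULT_GRID_SIZE", "DEFAULT_N_MIN", "SPAN_SCHEDULE"]

DEFAULT_GRID_SIZE = 512
#: minimum number of local maxima for the null comparison to be meaningful
DEFAULT_N_MIN = 10
#: loess span schedule tried in order until the smoothed gap is unimodal
SPAN_SCHEDULE = np.round(np.arange(0.10, 1.0001, 0.05), 2)


def local_maxima(profile: SpeedProfile) -> np.ndarray:
    """Speeds of samples strictly faster than both immediate neighbours.

    Comparisons are made only between mutually valid samples: a sample next
    to a missing/boundary sample cannot be a local maximum, and plateaus fail
    the strict inequality.
    """
    s, m = profile.speed, profile.valid
    if len(s) < 3:
        return np.array([])
    ok = m[1:-1] & m[:-2] & m[2:]
    with np.errstate(invalid="ignore"):
        peak = ok & (s[1:-1] > s[:-2]) & (s[1:-1] > s[2:])
    return s[1:-1][peak]


def gap_curve(maxima: np.ndarray, grid_size: int = DEFAULT_GRID_SIZE):
    """Raw gap statistic on an even grid over the range of the maxima.

    For candidate speed v, S_obs(v) = #{m > v} and the uniform null expects
    S_null(v) = n * (max - v) / (max - min).  The gap is the difference of
    the two exceedance distributions as fractions,
    ``(S_null - S_obs) / n``: large where the observed maxima fall short of
    the uniform expectation, i.e. just above a dense cluster.  (A log-scale
    ratio here instead drifts the maximum into voids of the sparse saccadic
    tail, where both counts are tiny but their ratio is extreme.)

    Candidates are evenly spaced quantiles of the maxima (grid points follow
    the distribution's own density).  An even spacing in speed instead puts
    most candidates into the long sparse saccadic tail, where the handful of
    peak speeds carve secondary gap modes that no bandwidth can smooth away;
    on the quantile grid the tail holds few candidates and the curve is
    reliably unimodal at the cluster edge.

    Returns ``(grid, gap)`` or ``None`` when the range is degenerate.
    """
    maxima = np.asarray(maxima, dtype=float)
    n = len(maxima)
    vmin, vmax = maxima.min(), maxima.max()
    if not np.isfinite(vmin) or vmax <= vmin:
        return None
    srt = np.sort(maxima)
    # inverted-CDF quantiles return observed speeds at evenly spaced ranks,
    # making the curve exactly invariant under duplication of the sample
    grid = np.unique(np.quantile(srt, np.linspace(0.0, 1.0, grid_size),
                                 method="inverted_cdf"))
    s_obs = n - np.searchsorted(srt, grid, side="right")
    s_null = n * (vmax - grid) / (vmax - vmin)
    gap = (s_null - s_obs) / n
    return grid, gap


def loess_quadratic(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Locally weighted quadratic regression with tricube weights.

    Fits a degree-2 polynomial at every point of ``x`` to its ``k = ceil(span
    * n)`` nearest neighbours, weighted by ``(1 - (d/dmax)^3)^3``.  Assumes
    ``x`` sorted ascending (true for the gap grid).  Fits are solved as
    batched 3x3 normal equations for speed; a naive per-point weighted
    polyfit gives identical values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = int(np.ceil(span * n))
    k = min(max(k, 4), n)
    # nearest neighbours of a sorted x form a contiguous window; centre it,
    # then shift while the excluded point is closer than the farthest kept
    starts = np.clip(np.arange(n) - k // 2, 0, n - k)
    for _ in range(max(k, 2)):
        d_far_right = x[np.minimum(starts + k - 1, n - 1)] - x
        d_new_left = x - x[np.maximum(starts - 1, 0)]
        shift_left = (starts > 0) & (d_new_left < d_far_right)
        starts = np.where(shift_left, starts - 1, starts)
        d_far_left = x - x[starts]
        d_new_right = x[np.minimum(starts + k, n - 1)] - x
        shift_right = (starts + k < n) & (d_new_right < d_far_left)
        starts = np.where(shift_right, starts + 1, starts)
        if not (shift_left.any() or shift_right.any()):
            break
    idx = starts[:, None] + np.arange(k)[None, :]
    xw = x[idx]                       # (n, k)
    yw = y[idx]
    u = xw - x[:, None]
    dmax = np.abs(u).max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    w = (1.0 - np.clip(np.abs(u) / dmax, 0, 1) ** 3) ** 3
    # design matrix columns [1, u, u^2]; weighted normal equations A b = c
    pw = np.stack([np.ones_like(u), u, u * u], axis=2)   # (n, k, 3)
    wp = pw * w[:, :, None]
    A = np.einsum("nka,nkb->nab", wp, pw)
    c = np.einsum("nka,nk->na", wp, yw)
    # ridge jitter guards against singular windows (e.g. duplicated x)
    A += 1e-12 * np.eye(3)[None, :, :]
    beta = np.linalg.solve(A, c[:, :, None])[:, :, 0]
    return beta[:, 0]


def count_interior_maxima(y: np.ndarray) -> int:
    """Number of strict interior local maxima of a curve."""
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        return 0
    mid = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
    return int(mid.sum())


def smooth_until_unimodal(grid: np.ndarray, gap: np.ndarray,
                          spans=SPAN_SCHEDULE):
    """Smooth the gap curve at increasing spans until exactly one mode remains.

    Returns ``(smoothed, span, unimodal)``.  When no span on the schedule
    yields exactly one interior maximum the span-1.0 fit is returned with
    ``unimodal=False``.
    """
    last = None
    for span in spans:
        fit = loess_quadratic(grid, gap, float(span))
        last = (fit, float(span))
        if count_interior_maxima(fit) == 1:
            return fit, float(span), True
    fit, span = last
    return fit, span, count_interior_maxima(fit) == 1


def _mode_location(grid: np.ndarray, smoothed: np.ndarray) -> float:
    """Grid value at the (unique) interior local maximum; ties -> smallest."""
    y = smoothed
    mid = np.where((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0]
    if len(mid) == 0:
        return float("nan")
    return float(grid[mid[0] + 1])


def estimate_threshold(profile: SpeedProfile,
                       n_min: int = DEFAULT_N_MIN,
                       grid_size: int = DEFAULT_GRID_SIZE) -> ThresholdEstimate:
    """Estimate the per-trial velocity threshold from a speed profile.

    Composes :func:`local_maxima` -> :func:`gap_curve` ->
    :func:`smooth_until_unimodal`; the threshold is the candidate speed at the
    unique smoothed-gap maximum.  All failure modes (too few maxima,
    degenerate range, no unimodal fit) are reported via ``valid=False`` with
    an NaN threshold, never as exceptions.
    """
    maxima = local_maxima(profile)
    n = len(maxima)
    if n < n_min:
        return ThresholdEstimate(float("nan"), False, n, float("nan"),
                                 reason=f"only {n} local maxima (need {n_min})")
    gc = gap_curve(maxima, grid_size)
    if gc is None:
        return ThresholdEstimate(float("nan"), False, n, float("nan"),
                                 reason="degenerate speed range")
    grid, gap = gc
    smoothed, span, unimodal = smooth_until_unimodal(grid, gap)
    curve = pd.DataFrame({"speed": grid, "gap_raw": gap, "gap_smooth": smoothed})
    if not unimodal:
        return ThresholdEstimate(float("nan"), False, n, span, curve,
                                 reason="no unimodal smoothing on span schedule")
    thr = _mode_location(grid, smoothed)
    if not np.isfinite(thr):
        return ThresholdEstimate(float("nan"), False, n, span, curve,
                                 reason="no interior maximum")
    return ThresholdEstimate(thr, True, n, span, curve)


def duration_threshold_data_driven(initial_durations_ms,
                                   default_ms: float = 100.0,
                                   n_min: int = DEFAULT_N_MIN,
                                   grid_size: int = DEFAULT_GRID_SIZE):
    """Data-driven duration threshold from initial fixation durations.

    Applies the gap-statistic + smoothing machinery to the distribution of
    log durations and returns the duration (ms) at the smoothed gap maximum.
    Needs a lot of data to be reliable; with fewer than ``n_min`` durations
    or a degenerate sample it falls back to ``default_ms``.

    Returns ``(threshold_ms, fell_back)``.
    """
    d = np.asarray(list(initial_durations_ms), dtype=float)
    d = d[np.isfinite(d) & (d > 0)]
    if len(d) < n_min:
        return float(default_ms), True
    logd = np.log(d)
    gc = gap_curve(logd, grid_size)
    if gc is None:
        return float(default_ms), True
    grid, gap = gc
    smoothed, span, unimodal = smooth_until_unimodal(grid, gap)
    if not unimodal:
        return float(default_ms), True
    loc = _mode_location(grid, smoothed)
    if not np.isfinite(loc):
        return float(default_ms), True
    return float(np.exp(loc)), False


def threshold_diagnostics_frame(estimates: dict) -> pd.DataFrame:
    """Per-trial diagnostics table (trial, threshold, validity, n maxima, span)."""
    rows = []
    for tid, est in estimates.items():
        rows.append({"Trial": tid, "threshold": est.threshold,
                     "valid": est.valid, "n_local_maxima": est.n_local_maxima,
                     "bandwidth": est.bandwidth_used, "reason": est.reason})
    return pd.DataFrame(rows)
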