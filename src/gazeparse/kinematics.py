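"""Pixel-to-degree conversion, binocular merging, and the speed profile.

The speed profile is the common input of every velocity-based parser: the
per-sample eye speed in degrees of visual angle per second, computed with a
central difference (displacement between the preceding and succeeding sample
divided by the elapsed time).  No pre-filtering is applied; noise handling is
the adaptive threshold's job.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Geometry, GazeRecording, SpeedProfile, trial_groups

__all__ = ["px_to_deg", "cyclopean_merge", "speed_profile", "trial_speed_profile"]


def px_to_deg(dx, dy, geometry: Geometry, distance_mm):
    """Visual angle in degrees subtended by a pixel displacement.

    The displacement is converted to millimetres on the screen using the
    per-axis pixel pitch, then the full two-point subtense formula
    ``2 * atan(d_mm / (2 * distance_mm))`` is applied (no small-angle
    approximation).  All arguments broadcast.
    """
    distance_mm = np.asarray(distance_mm, dtype=float)
    if np.any(distance_mm <= 0):
        raise ValueError("distance_mm must be positive")
    mmx, mmy = geometry.mm_per_px
    d_mm = np.hypot(np.asarray(dx, dtype=float) * mmx,
                    np.asarray(dy, dtype=float) * mmy)
    return np.degrees(2.0 * np.arctan2(d_mm, 2.0 * distance_mm))


def _merge_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mean where both valid, the valid one where only one is, NaN otherwise."""
    both = ~np.isnan(a) & ~np.isnan(b)
    out = np.where(both, 0.5 * (a + b), np.where(np.isnan(a), b, a))
    return out


def cyclopean_merge(recording: GazeRecording) -> pd.DataFrame:
    """Combine the two eyes into a single (cyclopean) sample series.

    Per sample: the mean of the two eyes when both are valid; the valid eye's
    coordinates when exactly one is; missing when both are.  The same rule is
    applied to the eye-to-screen distance, after which missing distances fall
    back to the trial median and finally to the geometry's default distance
    (distance varies slowly relative to gaze, so a per-trial fallback is
    safe).

    Returns a frame with columns ``trial, time, x, y, dist``.
    """
    s = recording.samples
    x = _merge_pair(s["x_left"].to_numpy(float), s["x_right"].to_numpy(float))
    y = _merge_pair(s["y_left"].to_numpy(float), s["y_right"].to_numpy(float))
    # a sample is valid only if both coordinates are; enforce jointly
    bad = np.isnan(x) | np.isnan(y)
    x[bad] = np.nan
    y[bad] = np.nan
    dist = _merge_pair(s["dist_left"].to_numpy(float),
                       s["dist_right"].to_numpy(float))
    out = pd.DataFrame({"trial": s["trial"].to_numpy(), "time": s["time"].to_numpy(float),
                        "x": x, "y": y, "dist": dist})
    # distance fallbacks, per trial
    filled = []
    for tid, g in trial_groups(out):
        d = g["dist"].to_numpy(float)
        if np.isnan(d).any():
            med = np.nanmedian(d) if np.isfinite(d).any() else np.nan
            fallback = med if np.isfinite(med) else recording.geometry.default_distance_mm
            d = np.where(np.isnan(d), fallback, d)
            g = g.assign(dist=d)
        filled.append(g)
    return pd.concat(filled, ignore_index=True)


def trial_speed_profile(x: np.ndarray, y: np.ndarray, time_ms: np.ndarray,
                        dist_mm: np.ndarray, geometry: Geometry) -> SpeedProfile:
    """Central-difference speed (deg/s) for one trial's cyclopean samples.

    speed[i] = angle(p[i+1] - p[i-1]) / (t[i+1] - t[i-1]); invalid at the
    trial boundaries and wherever the sample itself or either neighbour is
    missing.  A trial with fewer than 3 samples yields an all-invalid
    profile.
    """
    n = len(x)
    speed = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if n < 3:
        return SpeedProfile(speed, valid)
    dx = x[2:] - x[:-2]
    dy = y[2:] - y[:-2]
    dt = (time_ms[2:] - time_ms[:-2]) / 1000.0  # seconds
    deg = px_to_deg(dx, dy, geometry, dist_mm[1:-1])
    with np.errstate(invalid="ignore"):
        speed[1:-1] = deg / dt
    # a speed is attributed to sample i only if i and both neighbours exist
    ok = ~np.isnan(x) & ~np.isnan(y)
    valid[1:-1] = ok[2:] & ok[1:-1] & ok[:-2]
    speed[~valid] = np.nan
    return SpeedProfile(speed, valid)


def speed_profile(cyclopean: pd.DataFrame, geometry: Geometry) -> SpeedProfile:
    """Speed profile over a multi-trial cyclopean frame (per-trial boundaries)."""
    speeds = np.full(len(cyclopean), np.nan)
    valids = np.zeros(len(cyclopean), dtype=bool)
    pos = 0
    for tid, g in trial_groups(cyclopean):
        prof = trial_speed_profile(g["x"].to_numpy(float), g["y"].to_numpy(float),
                                   g["time"].to_numpy(float),
                                   g["dist"].to_numpy(float), geometry)
        speeds[pos:pos + len(g)] = prof.speed
        valids[pos:pos + len(g)] = prof.valid
        pos += len(g)
    return SpeedProfile(speeds, valids)
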