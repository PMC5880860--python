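"""Event parsing: six-step adaptive pipeline and the comparison baselines.

The primary (``gazepath``) method turns a trial of raw binocular samples
into fixations and saccades in six steps:

1. merge the two eyes into a cyclopean signal;
2. estimate the trial's velocity threshold from the distribution of local
   speed maxima (see :mod:`gazeparse.threshold`);
3. interpolate short missing-data runs, but only when the bridging velocity
   across the gap stays below the threshold (no saccade during signal loss);
4. classify samples below the threshold as fixation candidates, above as
   saccade candidates, and cut candidate events at label changes;
5. merge successive fixations whose spatial extents (convex hulls) overlap —
   low precision splits single fixations, this heals them;
6. drop fixations shorter than the duration threshold (default 100 ms).

Also implemented, for comparison: ``mould`` (adaptive velocity threshold +
data-driven duration threshold, no interpolation or merging), ``mouldDur``
(adaptive velocity, fixed 100-ms duration), ``velocity`` (fixed 35 deg/s),
and ``dispersion`` (running-centroid radius, Tobii Clearview style).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .core import (ConfigurationError, GazeEvent, GazeRecording,
                   SpeedProfile, ThresholdEstimate)
from . import kinematics, threshold as thr, quality

METHODS = ("gazepath", "mould", "mouldDur", "dispersion", "velocity")


@dataclass(frozen=True)
class ParserConfig:
    """Parsing method and its thresholds.

    Defaults follow the published tool: 250-ms maximum interpolated gap
    (saccade programming takes ~200 ms, so longer losses may hide one),
    100-ms duration threshold, 35 deg/s fixed velocity threshold for the
    ``velocity`` baseline, and a 0.9-degree radius for the ``dispersion``
    baseline.
    """

    method: str = "gazepath"
    interpolation_max_gap_ms: float = 250.0
    duration_threshold_ms: float = 100.0
    fixed_velocity_threshold: float = 35.0
    dispersion_radius_deg: float = 0.9
    n_min_local_maxima: int = thr.DEFAULT_N_MIN
    # data-driven duration thresholds need a lot of data; below this many
    # initial fixation durations the mould method falls back to the default
    duration_n_min: int = 50
    grid_size: int = thr.DEFAULT_GRID_SIZE

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(
                f"unknown method {self.method!r}; choose one of {METHODS}")
        for name in ("interpolation_max_gap_ms", "duration_threshold_ms",
                     "fixed_velocity_threshold", "dispersion_radius_deg"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# step 3: gap interpolation

def interpolate_gaps(trial: pd.DataFrame, estimate: ThresholdEstimate,
                     max_gap_ms: float, period_ms: float, geometry):
    """Fill short missing-data runs whose bridging velocity is sub-threshold.

    A maximal run of missing samples is filled linearly in x and y iff its
    duration (run length x nominal sample period) is strictly shorter than
    ``max_gap_ms`` AND the straight-line speed between the flanking measured
    samples does not exceed the velocity threshold.  Runs touching the trial
    edge, long runs, and fast-bridge runs are left untouched.  Returns
    ``(frame, interpolated_mask)``; with an invalid threshold estimate the
    input is returned unchanged.
    """
    x = trial["x"].to_numpy(float).copy()
    y = trial["y"].to_numpy(float).copy()
    t = trial["time"].to_numpy(float)
    dist = trial["dist"].to_numpy(float)
    filled = np.zeros(len(x), dtype=bool)
    if not estimate.valid:
        return trial.copy(), filled
    missing = np.isnan(x) | np.isnan(y)
    n = len(x)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and missing[j + 1]:
            j += 1
        if i > 0 and j < n - 1:  # interior run with both flanks
            dur = (j - i + 1) * period_ms
            if dur < max_gap_ms:
                dt_s = (t[j + 1] - t[i - 1]) / 1000.0
                deg = kinematics.px_to_deg(x[j + 1] - x[i - 1],
                                           y[j + 1] - y[i - 1], geometry,
                                           0.5 * (dist[i - 1] + dist[j + 1]))
                if deg / dt_s <= estimate.threshold:
                    idx = np.arange(i, j + 1)
                    x[idx] = np.interp(t[idx], [t[i - 1], t[j + 1]],
                                       [x[i - 1], x[j + 1]])
                    y[idx] = np.interp(t[idx], [t[i - 1], t[j + 1]],
                                       [y[i - 1], y[j + 1]])
                    filled[idx] = True
        i = j + 1
    out = trial.copy()
    out["x"] = x
    out["y"] = y
    return out, filled


# ---------------------------------------------------------------------------
# step 4: velocity classification

def classify_by_velocity(profile: SpeedProfile, velocity_threshold: float
                         ) -> np.ndarray:
    """Label each sample 'f' (below threshold), 's' (at/above), or 'g' (gap)."""
    labels = np.full(len(profile.speed), "g", dtype="<U1")
    with np.errstate(invalid="ignore"):
        labels[profile.valid & (profile.speed < velocity_threshold)] = "f"
        labels[profile.valid & (profile.speed >= velocity_threshold)] = "s"
    return labels


def runs_to_events(labels: np.ndarray, time_ms: np.ndarray, period_ms: float,
                   trial_id=None) -> list[GazeEvent]:
    """Maximal runs of equal labels become candidate events (gaps dropped).

    Event timing is half-open on the sample clock: start at the first
    constituent sample's timestamp, end one nominal sample period after the
    last one's, so durations sum cleanly.
    """
    events = []
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        if labels[i] in ("f", "s"):
            events.append(GazeEvent(kind=str(labels[i]),
                                    start_ms=float(time_ms[i]),
                                    end_ms=float(time_ms[j]) + period_ms,
                                    first_sample=i, last_sample=j,
                                    trial=trial_id))
        i = j + 1
    return events


# ---------------------------------------------------------------------------
# step 5: merge spatially overlapping successive fixations

def _fixation_polygon(xs: np.ndarray, ys: np.ndarray,
                      fallback_radius: float) -> BaseGeometry:
    """Convex hull of a fixation's samples; degenerate hulls become discs."""
    pts = np.column_stack([xs, ys])
    pts = np.unique(pts[~np.isnan(pts).any(axis=1)], axis=0)
    if len(pts) >= 3:
        hull = shapely.convex_hull(shapely.multipoints(pts))
        if hull.area > 0:
            return hull
    if len(pts) == 0:
        return Point(0.0, 0.0).buffer(fallback_radius)
    cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
    return Point(cx, cy).buffer(max(fallback_radius, 1e-9))


def _median_rms_px(events: list[GazeEvent], x: np.ndarray, y: np.ndarray) -> float:
    rms = []
    for ev in events:
        if ev.kind != "f" or ev.n_samples < 2:
            continue
        xs = x[ev.first_sample:ev.last_sample + 1]
        ys = y[ev.first_sample:ev.last_sample + 1]
        d2 = np.diff(xs) ** 2 + np.diff(ys) ** 2
        d2 = d2[~np.isnan(d2)]
        if len(d2):
            rms.append(np.sqrt(d2.mean()))
    return float(np.median(rms)) if rms else 1e-6


def merge_overlapping_fixations(events: list[GazeEvent], x: np.ndarray,
                                y: np.ndarray) -> list[GazeEvent]:
    """Merge successive fixations whose spatial extents intersect.

    The spatial extent is the convex hull of the fixation's sample
    coordinates (fixations with fewer than three distinct points use a disc
    of radius one median intra-fixation RMS around the centroid).  When two
    successive fixations — ignoring intervening saccade/gap material —
    overlap, they and everything between them become one fixation; this is
    repeated to a fixed point.
    """
    events = [replace(ev) for ev in events]
    fallback = _median_rms_px(events, x, y)
    cache: dict[tuple[int, int], BaseGeometry] = {}

    def poly(ev: GazeEvent) -> BaseGeometry:
        key = (ev.first_sample, ev.last_sample)
        if key not in cache:
            cache[key] = _fixation_polygon(x[ev.first_sample:ev.last_sample + 1],
                                           y[ev.first_sample:ev.last_sample + 1],
                                           fallback)
        return cache[key]

    changed = True
    while changed:
        changed = False
        fix_idx = [i for i, ev in enumerate(events) if ev.kind == "f"]
        for a, b in zip(fix_idx, fix_idx[1:]):
            if poly(events[a]).intersects(poly(events[b])):
                ea, eb = events[a], events[b]
                merged = GazeEvent(kind="f", start_ms=ea.start_ms,
                                   end_ms=eb.end_ms,
                                   first_sample=ea.first_sample,
                                   last_sample=eb.last_sample,
                                   trial=ea.trial)
                events = events[:a] + [merged] + events[b + 1:]
                changed = True
                break
    return events


# ---------------------------------------------------------------------------
# step 6: duration threshold

def apply_duration_threshold(events: list[GazeEvent],
                             min_duration_ms: float) -> list[GazeEvent]:
    """Drop fixations shorter than the threshold (keep iff duration >= it).

    Removed fixations are simply unclassified — their samples rejoin no
    event; saccades are untouched.  Surviving events are re-ranked 1-based.
    """
    kept = [ev for ev in events
            if ev.kind != "f" or ev.duration_ms >= min_duration_ms]
    for rank, ev in enumerate(sorted(kept, key=lambda e: e.start_ms), start=1):
        ev.order = rank
    return kept


# ---------------------------------------------------------------------------
# the dispersion baseline (I-DT, running centroid)

def _dispersion_parse(trial: pd.DataFrame, radius_deg: float, geometry,
                      period_ms: float, trial_id) -> list[GazeEvent]:
    """I-DT with a running centroid: a fixation grows while every new sample
    stays within ``radius_deg`` of the centroid so far; the sample that
    exceeds it seeds the next window.  Missing samples end the window.  Only
    fixations are classified (the dispersion rule has no saccade model)."""
    x = trial["x"].to_numpy(float)
    y = trial["y"].to_numpy(float)
    t = trial["time"].to_numpy(float)
    dist = trial["dist"].to_numpy(float)
    n = len(x)
    valid = ~np.isnan(x) & ~np.isnan(y)
    events = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        cx, cy, cnt = x[i], y[i], 1
        j = i
        while j + 1 < n and valid[j + 1]:
            off = kinematics.px_to_deg(x[j + 1] - cx, y[j + 1] - cy,
                                       geometry, dist[j + 1])
            if off > radius_deg:
                break
            j += 1
            cnt += 1
            cx += (x[j] - cx) / cnt
            cy += (y[j] - cy) / cnt
        events.append(GazeEvent(kind="f", start_ms=float(t[i]),
                                end_ms=float(t[j]) + period_ms,
                                first_sample=i, last_sample=j,
                                trial=trial_id))
        i = j + 1
    return events


# ---------------------------------------------------------------------------
# the full per-trial pipeline

@dataclass
class TrialParse:
    """Result of parsing one trial: events, diagnostics, and the sample
    frame the events index into (post-interpolation for ``gazepath``)."""

    trial: object
    events: list[GazeEvent]
    estimate: ThresholdEstimate | None
    velocity_threshold: float
    duration_threshold_ms: float
    samples: pd.DataFrame | None = None
    interpolated: np.ndarray | None = None
    duration_fallback: bool = False


def parse_trial(cyclo_trial: pd.DataFrame, config: ParserConfig,
                geometry, period_ms: float, trial_id=None) -> TrialParse:
    """Parse one trial of cyclopean samples with the configured method.

    Trials whose adaptive threshold cannot be estimated yield zero events
    and carry the invalid estimate as a diagnostic.
    """
    method = config.method
    t = cyclo_trial["time"].to_numpy(float)

    if method == "dispersion":
        events = _dispersion_parse(cyclo_trial, config.dispersion_radius_deg,
                                   geometry, period_ms, trial_id)
        events = apply_duration_threshold(events, config.duration_threshold_ms)
        return TrialParse(trial_id, events, None, float("nan"),
                          config.duration_threshold_ms, cyclo_trial)

    if method == "velocity":
        profile = kinematics.trial_speed_profile(
            cyclo_trial["x"].to_numpy(float), cyclo_trial["y"].to_numpy(float),
            t, cyclo_trial["dist"].to_numpy(float), geometry)
        events = runs_to_events(
            classify_by_velocity(profile, config.fixed_velocity_threshold),
            t, period_ms, trial_id)
        events = apply_duration_threshold(events, config.duration_threshold_ms)
        return TrialParse(trial_id, events, None,
                          config.fixed_velocity_threshold,
                          config.duration_threshold_ms, cyclo_trial)

    # adaptive methods: estimate the velocity threshold on the raw speed
    profile = kinematics.trial_speed_profile(
        cyclo_trial["x"].to_numpy(float), cyclo_trial["y"].to_numpy(float),
        t, cyclo_trial["dist"].to_numpy(float), geometry)
    est = thr.estimate_threshold(profile, n_min=config.n_min_local_maxima,
                                 grid_size=config.grid_size)
    if not est.valid:
        return TrialParse(trial_id, [], est, float("nan"),
                          config.duration_threshold_ms, cyclo_trial)

    interp_mask = None
    work = cyclo_trial
    if method == "gazepath":
        work, interp_mask = interpolate_gaps(
            cyclo_trial, est, config.interpolation_max_gap_ms, period_ms,
            geometry)
        profile = kinematics.trial_speed_profile(
            work["x"].to_numpy(float), work["y"].to_numpy(float), t,
            work["dist"].to_numpy(float), geometry)

    events = runs_to_events(classify_by_velocity(profile, est.threshold),
                            t, period_ms, trial_id)

    if method == "gazepath":
        events = merge_overlapping_fixations(
            events, work["x"].to_numpy(float), work["y"].to_numpy(float))

    fallback = False
    if method == "mould":
        durations = [ev.duration_ms for ev in events if ev.kind == "f"]
        dur_thr, fallback = thr.duration_threshold_data_driven(
            durations, default_ms=config.duration_threshold_ms,
            n_min=config.duration_n_min)
    else:
        dur_thr = config.duration_threshold_ms

    events = apply_duration_threshold(events, dur_thr)
    return TrialParse(trial_id, events, est, est.threshold, dur_thr, work,
                      interp_mask, fallback)


def parse_recording(recording: GazeRecording, config: ParserConfig
                    ) -> tuple[pd.DataFrame, list[TrialParse]]:
    """Parse every trial of a recording into the output event table.

    Returns the event table (schema of :data:`gazeparse.io.EVENT_COLUMNS`,
    extras appended after Trial) and the per-trial diagnostics.
    """
    from . import io as gio  # deferred: io imports events for filtering

    cyclo = kinematics.cyclopean_merge(recording)
    period = recording.period_ms
    rows = []
    parses = []
    extra_names = sorted({k for d in recording.extras.values() for k in d})
    for tid in recording.trial_ids():
        g = cyclo[cyclo["trial"] == tid].reset_index(drop=True)
        tp = parse_trial(g, config, recording.geometry, period, tid)
        parses.append(tp)
        work = tp.samples if tp.samples is not None else g
        for ev in sorted(tp.events, key=lambda e: e.start_ms):
            stat = quality.event_stats(ev, work, recording.geometry)
            row = {"Participant": recording.participant_id, "Value": ev.kind,
                   "Duration": ev.duration_ms, "Start": ev.start_ms,
                   "End": ev.end_ms, "mean_x": stat["mean_x"],
                   "mean_y": stat["mean_y"],
                   "sdPOGsacAMP": stat["sdPOGsacAMP"], "RMS": stat["RMS"],
                   "Order": ev.order, "Trial": tid}
            for name in extra_names:
                row[name] = recording.extras.get(tid, {}).get(name)
            rows.append(row)
    cols = gio.EVENT_COLUMNS + extra_names
    table = pd.DataFrame(rows, columns=cols)
    return table, parses


# ---------------------------------------------------------------------------
# cross-method comparison

def compare_parsings(a: pd.DataFrame, b: pd.DataFrame,
                     tolerance_ms: float = 2.0) -> pd.DataFrame:
    """Flag, for every fixation of ``a``, splits and non-classification in ``b``.

    A fixation F of ``a`` is *split* by ``b`` when two or more fixations of
    ``b`` lie (within the tolerance) inside F's time span; it is *unmatched*
    when no fixation of ``b`` overlaps it at all.  The tolerance absorbs
    onset/offset jitter of about one sample so genuine splits are not masked.
    The comparison is one-directional; call with the tables swapped for the
    other direction.
    """
    ta, tb = set(a["Trial"].unique()), set(b["Trial"].unique())
    if ta != tb:
        raise ValueError(f"trial sets differ: {sorted(ta)} vs {sorted(tb)}")
    out = []
    for tid in a["Trial"].unique():
        fa = a[(a["Trial"] == tid) & (a["Value"] == "f")]
        fb = b[(b["Trial"] == tid) & (b["Value"] == "f")]
        bs = fb["Start"].to_numpy(float)
        be = fb["End"].to_numpy(float)
        for _, row in fa.iterrows():
            within = ((bs >= row["Start"] - tolerance_ms)
                      & (be <= row["End"] + tolerance_ms)).sum()
            overlap = ((bs < row["End"]) & (be > row["Start"])).sum()
            out.append({"Trial": tid, "Start": row["Start"], "End": row["End"],
                        "n_contained": int(within),
                        "split_by_other": int(within) >= 2,
                        "unmatched": int(overlap) == 0})
    return pd.DataFrame(out,
                        columns=["Trial", "Start", "End", "n_contained",
                                 "split_by_other", "unmatched"])


def comparison_summary(a: pd.DataFrame, b: pd.DataFrame,
                       tolerance_ms: float = 2.0) -> pd.DataFrame:
    """Two-directional totals: fixations, splits, extra fixations, unmatched."""
    rows = []
    for name, (p, q) in (("a_vs_b", (a, b)), ("b_vs_a", (b, a))):
        flags = compare_parsings(p, q, tolerance_ms)
        splits = flags["split_by_other"]
        extra = (flags.loc[splits, "n_contained"] - 1).sum() if splits.any() else 0
        rows.append({"direction": name, "n_fixations": len(flags),
                     "n_split": int(splits.sum()),
                     "n_extra_from_splits": int(extra),
                     "n_unmatched": int(flags["unmatched"].sum())})
    return pd.DataFrame(rows)
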