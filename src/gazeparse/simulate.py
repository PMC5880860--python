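"""Ground-truth gaze simulator.

Generates binocular recordings of a piecewise fixation/saccade scanpath with
known event boundaries, so every parser can be validated without external
data.  The generative model:

* fixation durations are lognormal (median 700 ms, log-SD 0.3 by default —
  free-viewing-like, with negligible mass under the 100-ms duration
  threshold so the true event count is recoverable);
* fixation centres are uniform over the stimulus, redrawn until the saccade
  to the next centre is at least ``min_saccade_amplitude_deg`` (default 5 —
  comfortably above the velocity floor at any noise level generated here);
* saccade durations follow the main sequence ``duration = 2.2 ms/deg x
  amplitude + 21 ms`` with a raised-cosine speed profile (standard
  oculomotor phenomenology; configurable, not fitted to any dataset);
* the trial is tiled exactly: the last drawn fixation is stretched to the
  trial end, so ground truth never contains a truncated fragment whose
  classification would be ambiguous at the duration threshold;
* measurement noise is isotropic Gaussian; ``noise_sd_deg`` is the pooled
  two-dimensional SD (same scale as the sdPOG statistic the package
  reports), i.e. each axis gets SD ``noise_sd_deg / sqrt(2)`` converted to
  pixels at the viewing distance, independently per eye; the right eye is
  the left eye plus a fixed interocular offset, before noise;
* missing-data flicker is a two-state (valid/missing) process with
  geometric run lengths of configurable means, independent per eye so that
  binocular merging is genuinely exercised.

Ground-truth median fixation duration is independent of the noise and
flicker settings by construction, which is what makes quality-decorrelation
checks on simulated cohorts meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Geometry, GazeRecording

__all__ = ["SimulationSpec", "GroundTruth", "simulate", "degrade",
           "default_geometry", "simulated_column_map"]


def default_geometry() -> Geometry:
    """17-inch-monitor-like setup: 1280x1024 px, 340x270 mm, 600 mm away
    (the stimulus spans roughly 32 x 25 degrees)."""
    return Geometry(screen_px=(1280, 1024), stimulus_px=(1280, 1024),
                    stimulus_mm=(340, 270), default_distance_mm=600.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters of a simulated recording (see module docstring)."""

    sampling_rate: float = 500.0
    n_trials: int = 10
    trial_duration_ms: float = 8000.0
    fixation_median_ms: float = 700.0
    fixation_log_sd: float = 0.3
    min_saccade_amplitude_deg: float = 5.0
    saccade_ms_per_deg: float = 2.2
    saccade_intercept_ms: float = 21.0
    noise_sd_deg: float = 0.15
    mean_valid_run_ms: float | None = None   # None = no flicker
    mean_missing_run_ms: float = 100.0
    interocular_offset_px: tuple[float, float] = (5.0, 0.0)
    geometry: Geometry = field(default_factory=default_geometry)

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "trial_duration_ms",
                     "fixation_median_ms", "fixation_log_sd",
                     "saccade_ms_per_deg", "mean_missing_run_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")


@dataclass
class GroundTruth:
    """True event sequence behind a simulated recording.

    ``events`` has one row per true event (trial, kind, start, end, cx, cy);
    ``labels`` is the per-sample true label ('f'/'s') aligned with the
    recording's samples.
    """

    events: pd.DataFrame
    labels: np.ndarray
    spec: SimulationSpec

    def fixation_count(self, trial) -> int:
        e = self.events
        return int(((e["trial"] == trial) & (e["kind"] == "f")).sum())


def _deg_to_px(deg: float, geometry: Geometry, distance_mm: float
               ) -> tuple[float, float]:
    """Per-axis pixel length of a small angle at the viewing distance."""
    mm = distance_mm * np.tan(np.radians(deg))
    mmx, mmy = geometry.mm_per_px
    return mm / mmx, mm / mmy


def _amplitude_deg(p, q, geometry: Geometry, distance_mm: float) -> float:
    mmx, mmy = geometry.mm_per_px
    d_mm = np.hypot((q[0] - p[0]) * mmx, (q[1] - p[1]) * mmy)
    return np.degrees(2 * np.arctan2(d_mm, 2 * distance_mm))


def _raised_cosine_position(tau: np.ndarray) -> np.ndarray:
    """Fraction of the saccade path covered at normalised time tau in [0,1]
    under a raised-cosine speed profile (integral of 0.5*(1 - cos 2*pi*tau))."""
    return tau - np.sin(2 * np.pi * tau) / (2 * np.pi)


def _plan_trial(spec: SimulationSpec, rng: np.random.Generator):
    """Alternating fixation/saccade event plan tiling one trial exactly.

    Fixation/saccade pairs are drawn until the next pair would overrun the
    trial; the final fixation is then stretched to the trial end, so the
    ground truth contains no truncated event fragment.
    """
    geom = spec.geometry
    dist = geom.default_distance_mm
    sw, sh = geom.stimulus_px
    ox = (geom.screen_px[0] - sw) / 2
    oy = (geom.screen_px[1] - sh) / 2

    def draw_center():
        return (ox + rng.uniform(0, sw), oy + rng.uniform(0, sh))

    mu = np.log(spec.fixation_median_ms)
    events = []
    t = 0.0
    center = draw_center()
    guard = 0
    while True:
        guard += 1
        if guard > 100000:
            raise ValueError("fixation-duration law cannot fill the trial")
        dur = float(np.exp(rng.normal(mu, spec.fixation_log_sd)))
        nxt = draw_center()
        amp = _amplitude_deg(center, nxt, geom, dist)
        tries = 0
        while amp < spec.min_saccade_amplitude_deg and tries < 1000:
            nxt = draw_center()
            amp = _amplitude_deg(center, nxt, geom, dist)
            tries += 1
        sdur = spec.saccade_ms_per_deg * amp + spec.saccade_intercept_ms
        if t + dur + sdur >= spec.trial_duration_ms:
            remaining = spec.trial_duration_ms - t
            if remaining < 300.0 and len(events) >= 2:
                # too short to stand as a fixation of its own: drop the
                # preceding saccade and stretch the previous fixation instead
                events.pop()
                kind, t0, _, p, q = events.pop()
                events.append((kind, t0, spec.trial_duration_ms, p, q))
            else:
                events.append(("f", t, spec.trial_duration_ms, center, center))
            break
        events.append(("f", t, t + dur, center, center))
        t += dur
        events.append(("s", t, t + sdur, center, nxt))
        t += sdur
        center = nxt
    return events


def _flicker_mask(n: int, period_ms: float, mean_valid_ms: float,
                  mean_missing_ms: float, rng: np.random.Generator
                  ) -> np.ndarray:
    """Two-state missingness: True = missing.  Geometric run lengths."""
    p_lose = min(1.0, period_ms / mean_valid_ms)
    p_regain = min(1.0, period_ms / mean_missing_ms)
    mask = np.zeros(n, dtype=bool)
    state = rng.random() < mean_missing_ms / (mean_valid_ms + mean_missing_ms)
    u = rng.random(n)
    for i in range(n):
        mask[i] = state
        if state:
            state = not (u[i] < p_regain)
        else:
            state = u[i] < p_lose
    return mask


def simulate(spec: SimulationSpec, seed: int | None = None,
             participant_id: str = "sim") -> tuple[GazeRecording, GroundTruth]:
    """Generate a binocular recording plus its ground truth.

    Deterministic under a fixed seed.  Samples are taken at
    ``k / sampling_rate``; each sample's true label is that of the event
    covering its timestamp.  Each trial draws its event plan and its
    measurement noise from separate substreams, so the true event sequence
    is identical across sampling rates and noise settings.
    """
    root = np.random.SeedSequence(seed)
    trial_seeds = root.spawn(spec.n_trials)
    geom = spec.geometry
    dist = geom.default_distance_mm
    period = 1000.0 / spec.sampling_rate
    n_per_trial = int(round(spec.trial_duration_ms / period))

    # noise_sd_deg is the pooled 2-D SD: each axis carries sd/sqrt(2)
    sd_px_x, sd_px_y = _deg_to_px(spec.noise_sd_deg / np.sqrt(2), geom, dist) \
        if spec.noise_sd_deg > 0 else (0.0, 0.0)

    frames, truth_rows, labels_all = [], [], []
    for trial in range(1, spec.n_trials + 1):
        plan_ss, noise_ss = trial_seeds[trial - 1].spawn(2)
        plan = _plan_trial(spec, np.random.default_rng(plan_ss))
        rng = np.random.default_rng(noise_ss)
        t = np.arange(n_per_trial) * period
        x = np.empty(n_per_trial)
        y = np.empty(n_per_trial)
        labels = np.empty(n_per_trial, dtype="<U1")
        for kind, t0, t1, p, q in plan:
            sel = (t >= t0) & (t < t1)
            if kind == "f":
                x[sel], y[sel] = p
            else:
                tau = (t[sel] - t0) / (t1 - t0)
                frac = _raised_cosine_position(tau)
                x[sel] = p[0] + (q[0] - p[0]) * frac
                y[sel] = p[1] + (q[1] - p[1]) * frac
            labels[sel] = kind
            truth_rows.append({"trial": trial, "kind": kind, "start": t0,
                               "end": t1, "cx": q[0], "cy": q[1]})
        off = spec.interocular_offset_px
        xl = x + rng.normal(0, sd_px_x, n_per_trial) if sd_px_x else x.copy()
        yl = y + rng.normal(0, sd_px_y, n_per_trial) if sd_px_y else y.copy()
        xr = x + off[0] + (rng.normal(0, sd_px_x, n_per_trial) if sd_px_x else 0)
        yr = y + off[1] + (rng.normal(0, sd_px_y, n_per_trial) if sd_px_y else 0)
        dl = np.full(n_per_trial, float(dist))
        dr = np.full(n_per_trial, float(dist))
        if spec.mean_valid_run_ms is not None:
            for xs, ys, ds in ((xl, yl, dl), (xr, yr, dr)):
                miss = _flicker_mask(n_per_trial, period,
                                     spec.mean_valid_run_ms,
                                     spec.mean_missing_run_ms, rng)
                xs[miss] = np.nan
                ys[miss] = np.nan
                ds[miss] = np.nan
        frames.append(pd.DataFrame({
            "trial": trial, "time": t, "x_left": xl, "y_left": yl,
            "x_right": xr, "y_right": yr, "dist_left": dl, "dist_right": dr}))
        labels_all.append(labels)

    samples = pd.concat(frames, ignore_index=True)
    rec = GazeRecording(participant_id=participant_id, samples=samples,
                        sampling_rate=spec.sampling_rate, geometry=geom)
    truth = GroundTruth(events=pd.DataFrame(truth_rows),
                        labels=np.concatenate(labels_all), spec=spec)
    return rec, truth


def degrade(recording: GazeRecording, noise_sd_deg: float = 0.0,
            mean_valid_run_ms: float | None = None,
            mean_missing_run_ms: float = 100.0,
            seed: int | None = None) -> GazeRecording:
    """Add noise and/or flicker to an existing recording (input untouched).

    Noise SDs compose in quadrature across repeated calls; flicker removes
    samples without altering surviving coordinates.  With zero noise and no
    flicker this is the identity.
    """
    rng = np.random.default_rng(seed)
    s = recording.samples.copy(deep=True)
    geom = recording.geometry
    period = recording.period_ms
    if noise_sd_deg > 0:
        for xcol, ycol, dcol in (("x_left", "y_left", "dist_left"),
                                 ("x_right", "y_right", "dist_right")):
            x = s[xcol].to_numpy(float)
            y = s[ycol].to_numpy(float)
            d = s[dcol].to_numpy(float)
            d = np.where(np.isnan(d), geom.default_distance_mm, d)
            mm = d * np.tan(np.radians(noise_sd_deg / np.sqrt(2)))
            mmx, mmy = geom.mm_per_px
            ok = ~np.isnan(x)
            x[ok] += rng.normal(0, 1, ok.sum()) * (mm[ok] / mmx)
            y[ok] += rng.normal(0, 1, ok.sum()) * (mm[ok] / mmy)
            s[xcol] = x
            s[ycol] = y
    if mean_valid_run_ms is not None:
        for xcol, ycol, dcol in (("x_left", "y_left", "dist_left"),
                                 ("x_right", "y_right", "dist_right")):
            for tid in pd.unique(s["trial"]):
                sel = (s["trial"] == tid).to_numpy()
                miss = _flicker_mask(int(sel.sum()), period, mean_valid_run_ms,
                                     mean_missing_run_ms, rng)
                idx = np.where(sel)[0][miss]
                s.loc[idx, [xcol, ycol, dcol]] = np.nan
    return GazeRecording(participant_id=recording.participant_id,
                         samples=s, sampling_rate=recording.sampling_rate,
                         geometry=geom, extras=dict(recording.extras))


def drop_in_fixations(recording: GazeRecording, truth: GroundTruth,
                      n_dropouts: int, dropout_ms: tuple[float, float],
                      seed: int | None = None) -> GazeRecording:
    """Blank ``n_dropouts`` windows per trial, each fully inside a true
    fixation, to probe robustness handling.  Dropout lengths are uniform on
    ``dropout_ms``; both eyes are blanked together."""
    rng = np.random.default_rng(seed)
    s = recording.samples.copy(deep=True)
    period = recording.period_ms
    for tid in pd.unique(s["trial"]):
        fx = truth.events[(truth.events["trial"] == tid)
                          & (truth.events["kind"] == "f")]
        sel = np.where((s["trial"] == tid).to_numpy())[0]
        t = s.loc[sel, "time"].to_numpy(float)
        eligible = fx[(fx["end"] - fx["start"]) > dropout_ms[1] + 4 * period]
        if eligible.empty:
            continue
        picks = eligible.sample(n=min(n_dropouts, len(eligible)),
                                random_state=rng.integers(2 ** 31))
        for _, row in picks.iterrows():
            dur = rng.uniform(*dropout_ms)
            lo = row["start"] + 2 * period
            hi = row["end"] - dur - 2 * period
            if hi <= lo:
                continue
            t0 = rng.uniform(lo, hi)
            mask = (t >= t0) & (t < t0 + dur)
            cols = ["x_left", "y_left", "x_right", "y_right",
                    "dist_left", "dist_right"]
            s.loc[sel[mask], cols] = np.nan
    return GazeRecording(participant_id=recording.participant_id, samples=s,
                         sampling_rate=recording.sampling_rate,
                         geometry=recording.geometry,
                         extras=dict(recording.extras))


def simulated_column_map():
    """ColumnMap matching the raw CSVs written by :func:`write_raw_csv`."""
    from .core import ColumnMap
    return ColumnMap(x_left="x_left", y_left="y_left", x_right="x_right",
                     y_right="y_right", distance_left="dist_left",
                     distance_right="dist_right", trial="trial",
                     timestamp="time")


def write_raw_csv(recording: GazeRecording, path) -> None:
    """Write raw samples in the delimited dialect the reader understands."""
    recording.samples.to_csv(path, index=False, na_rep="NA")


def write_truth_csv(truth: GroundTruth, path) -> None:
    truth.events.to_csv(path, index=False)
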