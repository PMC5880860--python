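"""Reading raw eye-tracker text exports and writing parsed event tables.

Raw input is a delimited text file with one row per sample; a
:class:`~gazeparse.core.ColumnMap` names the relevant columns and the
missing-data tokens.  Output is a CSV whose columns appear in the fixed
order ``Participant, Value, Duration, Start, End, mean_x, mean_y,
sdPOGsacAMP, RMS, Order, Trial`` (extra kept variables appended after
Trial), available in four forms: everything, fixations only, complete
events only, or complete fixations only.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .core import (ColumnMap, ConfigurationError, DataError, Geometry,
                   GazeRecording, SAMPLE_COLUMNS)

EVENT_COLUMNS = ["Participant", "Value", "Duration", "Start", "End",
                 "mean_x", "mean_y", "sdPOGsacAMP", "RMS", "Order", "Trial"]

EXPORT_FORMS = ("all", "fixations_only", "complete_all", "complete_fixations")


def read_recording(path, colmap: ColumnMap, geometry: Geometry,
                   sampling_rate: float) -> GazeRecording:
    """Read one participant's raw samples into a :class:`GazeRecording`.

    The participant id is the file's base name.  Every configured missing
    token maps to NaN; a sample is missing iff any required coordinate of
    an eye is.  Timestamps are normalised to start at 0 within each trial
    and must be strictly increasing; ``extra_keep`` columns must be constant
    within each trial.
    """
    raw = pd.read_csv(path, sep=colmap.delimiter, decimal=colmap.decimal,
                      na_values=list(colmap.missing_value_tokens),
                      keep_default_na=True)
    needed = {"trial": colmap.trial, "timestamp": colmap.timestamp}
    for attr in ("x_left", "y_left", "x_right", "y_right",
                 "distance_left", "distance_right"):
        name = getattr(colmap, attr)
        if name is not None:
            needed[attr] = name
    for extra in colmap.extra_keep:
        needed[f"extra:{extra}"] = extra
    for role, name in needed.items():
        if name not in raw.columns:
            raise ConfigurationError(
                f"column {name!r} (mapped as {role}) not in header "
                f"{list(raw.columns)}")

    def num(colname):
        if colname is None:
            return np.full(len(raw), np.nan)
        return pd.to_numeric(raw[colname], errors="coerce").to_numpy(float)

    frame = pd.DataFrame({
        "trial": raw[colmap.trial].to_numpy(),
        "time": num(colmap.timestamp),
        "x_left": num(colmap.x_left), "y_left": num(colmap.y_left),
        "x_right": num(colmap.x_right), "y_right": num(colmap.y_right),
        "dist_left": num(colmap.distance_left),
        "dist_right": num(colmap.distance_right),
    })

    extras: dict = {}
    parts = []
    for tid in pd.unique(frame["trial"]):
        sel = frame["trial"] == tid
        g = frame[sel].copy()
        t = g["time"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"timestamps not strictly increasing in trial "
                            f"{tid!r} of {path}")
        g["time"] = t - t[0]
        parts.append(g)
        if colmap.extra_keep:
            ex = {}
            for name in colmap.extra_keep:
                vals = raw.loc[sel.to_numpy(), name].dropna().unique()
                if len(vals) > 1:
                    raise DataError(
                        f"extra column {name!r} varies within trial {tid!r}")
                ex[name] = vals[0] if len(vals) else None
            extras[tid] = ex

    samples = pd.concat(parts, ignore_index=True)[SAMPLE_COLUMNS]
    pid = os.path.splitext(os.path.basename(str(path)))[0]
    return GazeRecording(participant_id=pid, samples=samples,
                         sampling_rate=sampling_rate, geometry=geometry,
                         extras=extras)


def read_recordings(paths: Iterable, colmap: ColumnMap, geometry: Geometry,
                    sampling_rate: float) -> list[GazeRecording]:
    """Read several identically formatted files (header homogeneity is
    checked before any parsing starts)."""
    paths = list(paths)
    headers = []
    for p in paths:
        with open(p, "r", encoding="utf-8") as fh:
            headers.append(fh.readline().strip())
    if len(set(headers)) > 1:
        raise ConfigurationError("input files have heterogeneous headers; "
                                 "all files must share one format")
    return [read_recording(p, colmap, geometry, sampling_rate) for p in paths]


def _complete_mask(events: pd.DataFrame) -> pd.Series:
    """A fixation is complete iff immediately preceded AND followed by a
    saccade row in the same trial; a saccade iff between two fixations."""
    mask = pd.Series(False, index=events.index)
    for (_, _), g in events.groupby(["Participant", "Trial"], sort=False):
        vals = g["Value"].to_numpy()
        prev = np.concatenate([[""], vals[:-1]])
        nxt = np.concatenate([vals[1:], [""]])
        comp = ((vals == "f") & (prev == "s") & (nxt == "s")) \
            | ((vals == "s") & (prev == "f") & (nxt == "f"))
        mask.loc[g.index] = comp
    return mask


def filter_events(events: pd.DataFrame, form: str) -> pd.DataFrame:
    """Apply one of the four export forms to an event table."""
    if form not in EXPORT_FORMS:
        raise ConfigurationError(
            f"unknown form {form!r}; choose one of {EXPORT_FORMS}")
    if form == "all" or events.empty:
        return events.copy()
    if form == "fixations_only":
        return events[events["Value"] == "f"].copy()
    comp = _complete_mask(events)
    if form == "complete_all":
        return events[comp].copy()
    return events[comp & (events["Value"] == "f")].copy()


def write_events(events: pd.DataFrame, form: str, path) -> None:
    """Write an event table as CSV in the fixed schema order.

    An empty table produces a header-only file.
    """
    out = filter_events(events, form)
    fixed = [c for c in EVENT_COLUMNS if c in out.columns]
    extras = [c for c in out.columns if c not in EVENT_COLUMNS]
    out = out[fixed + extras]
    out.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read back an event CSV written by :func:`write_events`."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# configuration files

def load_config(path):
    """Load a YAML run configuration.

    Recognised top-level keys: ``columns`` (ColumnMap fields), ``geometry``
    (Geometry fields), ``sampling_rate``, and optional ``parser`` fields
    (method plus thresholds).  Returns ``(colmap, geometry, sampling_rate,
    parser_kwargs)``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    try:
        cols = cfg.get("columns", {})
        for key in ("missing_value_tokens", "extra_keep"):
            if key in cols and isinstance(cols[key], list):
                cols[key] = tuple(cols[key])
        colmap = ColumnMap(**cols)
        geo = cfg.get("geometry", {})
        for key in ("screen_px", "stimulus_px", "stimulus_mm"):
            if key in geo:
                geo[key] = tuple(geo[key])
        geometry = Geometry(**geo)
        rate = float(cfg["sampling_rate"])
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"bad config {path}: {exc}") from exc
    return colmap, geometry, rate, cfg.get("parser", {})
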