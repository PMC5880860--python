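"""Core data structures shared by all modules.

The central container is :class:`GazeRecording`, a per-participant table of
raw binocular gaze samples together with the screen/stimulus geometry needed
to convert pixel displacements into degrees of visual angle.  Parsed output
is represented as lists of :class:`GazeEvent` and, at the file boundary, as a
pandas DataFrame in the fixed output schema (see :mod:`gazeparse.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a column map, geometry or parser config is inconsistent."""


class DataError(ValueError):
    """Raised when an input file violates the data contract (e.g. timestamps)."""


@dataclass(frozen=True)
class Geometry:
    """Screen and stimulus geometry.

    Parameters
    ----------
    screen_px : (width, height) of the screen in pixels.
    stimulus_px : (width, height) of the stimulus area in pixels.
    stimulus_mm : (width, height) of the stimulus area in millimetres.
    default_distance_mm : eye-to-screen distance used when a recording carries
        no distance signal.

    The stimulus is assumed centred on the screen.  Pixel pitch may differ by
    axis; per-axis mm-per-pixel factors are exposed via :attr:`mm_per_px`.
    """

    screen_px: tuple[float, float]
    stimulus_px: tuple[float, float]
    stimulus_mm: tuple[float, float]
    default_distance_mm: float = 600.0

    def __post_init__(self) -> None:
        for name in ("screen_px", "stimulus_px", "stimulus_mm"):
            w, h = getattr(self, name)
            if w <= 0 or h <= 0:
                raise ConfigurationError(f"{name} must be positive, got {(w, h)}")
        if (self.stimulus_px[0] > self.screen_px[0]
                or self.stimulus_px[1] > self.screen_px[1]):
            raise ConfigurationError("stimulus_px must fit inside screen_px")
        if self.default_distance_mm <= 0:
            raise ConfigurationError("default_distance_mm must be positive")

    @property
    def mm_per_px(self) -> tuple[float, float]:
        return (self.stimulus_mm[0] / self.stimulus_px[0],
                self.stimulus_mm[1] / self.stimulus_px[1])


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from raw-export column names to the canonical sample fields.

    At least one eye's x/y pair plus the trial and timestamp columns must be
    named.  ``extra_keep`` columns must be constant within each trial and are
    carried through to the output table.
    """

    x_left: Optional[str] = None
    y_left: Optional[str] = None
    x_right: Optional[str] = None
    y_right: Optional[str] = None
    distance_left: Optional[str] = None
    distance_right: Optional[str] = None
    trial: str = "trial"
    timestamp: str = "time"
    missing_value_tokens: tuple[str, ...] = ("NA", "NaN", "", ".")
    delimiter: str = ","
    decimal: str = "."
    extra_keep: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        left_ok = self.x_left is not None and self.y_left is not None
        right_ok = self.x_right is not None and self.y_right is not None
        if not (left_ok or right_ok):
            raise ConfigurationError(
                "at least one eye needs both x and y columns named")
        if not self.trial or not self.timestamp:
            raise ConfigurationError("trial and timestamp columns are mandatory")

    @property
    def has_left(self) -> bool:
        return self.x_left is not None and self.y_left is not None

    @property
    def has_right(self) -> bool:
        return self.x_right is not None and self.y_right is not None


#: canonical sample-frame columns used throughout the package
SAMPLE_COLUMNS = ["trial", "time", "x_left", "y_left", "x_right", "y_right",
                  "dist_left", "dist_right"]


@dataclass
class GazeRecording:
    """Raw binocular samples for one participant.

    ``samples`` holds one row per sample with the canonical columns
    ``trial, time, x_left, y_left, x_right, y_right, dist_left, dist_right``;
    missing values are NaN.  Timestamps are in ms, normalised so each trial
    starts at 0, strictly increasing within trial.  ``extras`` maps each trial
    to its constant extra variables.
    """

    participant_id: str
    samples: pd.DataFrame
    sampling_rate: float
    geometry: Geometry
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ConfigurationError(f"samples frame lacks columns {missing}")

    @property
    def period_ms(self) -> float:
        """Nominal inter-sample interval in milliseconds."""
        return 1000.0 / self.sampling_rate

    def trial_ids(self) -> list:
        return list(pd.unique(self.samples["trial"]))

    def trial(self, trial_id) -> pd.DataFrame:
        out = self.samples[self.samples["trial"] == trial_id]
        if out.empty:
            raise KeyError(f"no such trial: {trial_id!r}")
        return out.reset_index(drop=True)


@dataclass
class SpeedProfile:
    """Per-sample eye speed in deg/s with a validity mask.

    ``speed[i]`` is defined by the central difference between samples i-1 and
    i+1; it is invalid at trial boundaries and wherever either neighbour is
    missing.
    """

    speed: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.speed.shape != self.valid.shape:
            raise ValueError("speed and valid must have identical shape")


@dataclass
class ThresholdEstimate:
    """Per-trial velocity threshold with diagnostics.

    ``valid`` is False when the trial had too few local speed maxima, a
    degenerate speed range, or no bandwidth produced a unimodal gap curve; in
    that case ``threshold`` is NaN.
    """

    threshold: float
    valid: bool
    n_local_maxima: int
    bandwidth_used: float
    gap_curve: Optional[pd.DataFrame] = None
    reason: str = ""


@dataclass
class GazeEvent:
    """A classified fixation ('f') or saccade ('s') within one trial."""

    kind: str
    start_ms: float
    end_ms: float
    first_sample: int
    last_sample: int
    trial: object = None
    order: int = 0
    mean_x: float = float("nan")
    mean_y: float = float("nan")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def n_samples(self) -> int:
        return self.last_sample - self.first_sample + 1


def trial_groups(samples: pd.DataFrame):
    """Yield (trial_id, frame) in file order without sorting trials."""
    for tid in pd.unique(samples["trial"]):
        yield tid, samples[samples["trial"] == tid].reset_index(drop=True)
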