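import numpy as np
import pandas as pd
import pytest

from gazeparse import Geometry, GazeRecording, ParserConfig, SimulationSpec, simulate


@pytest.fixture(scope="session")
def geometry():
    return Geometry(screen_px=(1280, 1024), stimulus_px=(1280, 1024),
                    stimulus_mm=(340, 270), default_distance_mm=600.0)


@pytest.fixture(scope="session")
def clean_sim():
    """One clean 500-Hz trial (noise 0.15 deg, no flicker) with ground truth."""
    spec = SimulationSpec(n_trials=1)
    return simulate(spec, seed=42)


@pytest.fixture(scope="session")
def quiet_sim():
    """A very low-noise trial where every parser should do well."""
    spec = SimulationSpec(n_trials=1, noise_sd_deg=0.02)
    return simulate(spec, seed=7)


def make_recording(geometry, x, y, time=None, trial=None, sampling_rate=500.0,
                   x_right=None, y_right=None, dist=600.0):
    """Hand-built monocular-or-binocular recording from coordinate arrays."""
    x = np.asarray(x, float)
    n = len(x)
    time = np.arange(n) * 1000.0 / sampling_rate if time is None else np.asarray(time, float)
    trial = np.ones(n) if trial is None else np.asarray(trial)
    frame = pd.DataFrame({
        "trial": trial, "time": time,
        "x_left": x, "y_left": np.asarray(y, float),
        "x_right": np.full(n, np.nan) if x_right is None else np.asarray(x_right, float),
        "y_right": np.full(n, np.nan) if y_right is None else np.asarray(y_right, float),
        "dist_left": np.full(n, float(dist)),
        "dist_right": np.full(n, np.nan),
    })
    return GazeRecording(participant_id="test", samples=frame,
                         sampling_rate=sampling_rate, geometry=geometry)


@pytest.fixture
def recording_factory(geometry):
    def factory(x, y, **kw):
        return make_recording(geometry, x, y, **kw)
    return factory
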