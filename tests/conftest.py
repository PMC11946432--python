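import numpy as np
import pytest

from roadhypno import fusion
from roadhypno.synthetic_data import SimConfig, generate_dataset
from roadhypno.timeline_io import (EventIntervals, MultimodalRecording,
                                   SampledSignal)


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A short-session configuration for fast unit tests."""
    return SimConfig(duration=90.0, n_recordings=4, seed=11)


@pytest.fixture(scope="session")
def small_recordings(small_sim_config):
    return generate_dataset(small_sim_config)


@pytest.fixture(scope="session")
def small_matrices(small_recordings):
    return [fusion.extract_features(r) for r in small_recordings]


@pytest.fixture()
def toy_recording() -> MultimodalRecording:
    """A tiny hand-built recording with known spans and one labelled interval."""
    rng = np.random.default_rng(0)
    eeg = SampledSignal(["c1", "c2"], 100.0, 0.0, rng.normal(size=(3000, 2)))
    eye = SampledSignal(
        ["pupil_diameter_left", "pupil_diameter_right", "gaze_velocity",
         "ipd", "valid"],
        100.0, 0.0,
        np.column_stack([
            4 + 0.1 * rng.normal(size=3000),
            4 + 0.1 * rng.normal(size=3000),
            np.abs(50 + 10 * rng.normal(size=3000)),
            62 + 0.05 * rng.normal(size=3000),
            np.ones(3000),
        ]),
    )
    veh = SampledSignal(["speed", "acceleration"], 10.0, 0.0,
                        np.column_stack([13 + rng.normal(size=300),
                                         rng.normal(size=300)]))
    labels = EventIntervals([(10.0, 20.0, "hypnosis")])
    return MultimodalRecording(eeg=eeg, eye=eye, vehicle=veh, labels=labels)
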