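import numpy as np
import pytest

from neoseize.core import EEGRecording
from neoseize.detector import ProbabilityTrace, predict_probabilities, train_model
from neoseize.features import extract_features
from neoseize.preprocess import make_epochs, resample_to_32hz
from neoseize.simulate import (
    SeizureEvent,
    SimulationConfig,
    channel_epoch_labels,
    simulate_recording,
)


def make_trace(per_channel, times_s=None, labels=None, duration_s=None):
    """Build a ProbabilityTrace directly from a channels x epochs array."""
    per_channel = np.asarray(per_channel, dtype=float)
    if per_channel.ndim == 1:
        per_channel = per_channel[None, :]
    n = per_channel.shape[1]
    if times_s is None:
        times_s = 4.0 + 4.0 * np.arange(n)
    if labels is None:
        labels = [f"ch{i}" for i in range(per_channel.shape[0])]
    return ProbabilityTrace(
        per_channel=per_channel,
        fused=per_channel.max(axis=0),
        times_s=np.asarray(times_s, dtype=float),
        channel_labels=list(labels),
        duration_s=duration_s,
    )


def sine_recording(freq_hz, duration_s=60.0, fs=32.0, labels=("F3-C3", "F4-C4"), amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    return EEGRecording(np.tile(x, (len(labels), 1)), fs, list(labels))


@pytest.fixture(scope="session")
def seizure_config():
    """One 240 s record with two strong discharges on known channels."""
    return SimulationConfig(
        duration_s=240.0,
        seed=7,
        seizure_events=[
            SeizureEvent(40.0, 100.0, 2.5, 100.0, (0, 1)),
            SeizureEvent(150.0, 210.0, 4.0, 100.0, (5, 6)),
        ],
    )


@pytest.fixture(scope="session")
def seizure_recording(seizure_config):
    return simulate_recording(seizure_config)


@pytest.fixture(scope="session")
def seizure_features(seizure_config, seizure_recording):
    rec, _ = seizure_recording
    epochs = make_epochs(resample_to_32hz(rec))
    return extract_features(epochs)


@pytest.fixture(scope="session")
def tiny_model(seizure_config, seizure_features):
    """A classifier trained on the single synthetic record (mechanics only)."""
    labels = channel_epoch_labels(seizure_config, seizure_features.epoch_start_s)
    return train_model(seizure_features, labels, seed=0)


@pytest.fixture(scope="session")
def tiny_trace(tiny_model, seizure_features):
    return predict_probabilities(tiny_model, seizure_features)
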