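import numpy as np
import pandas as pd
import pytest

import thetaflow as tf


def tone_recording(freq, fs=500.0, duration=10.0, amp=1.0, n_ch=1):
    """Pure sinusoid recording on one probe."""
    t = np.arange(int(duration * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq * t)
    samples = np.tile(sig[:, None], (1, n_ch))
    channels = pd.DataFrame({
        "label": [f"C{i+1}" for i in range(n_ch)],
        "region": ["FRO"] * n_ch,
        "probe": ["P1"] * n_ch,
        "contact_index": np.arange(1, n_ch + 1),
    })
    return tf.RawRecording(samples, fs, channels)


@pytest.fixture(scope="session")
def coupled_dataset():
    """60-trial session with strong NC->HC coupling at 100 ms lag."""
    cfg = tf.SimConfig(n_trials_per_condition=15, coupling_strength=0.8,
                       coupling_direction="nc->hc", seed=42)
    return tf.simulate_coupled_pair(cfg)


@pytest.fixture(scope="session")
def coupled_phases(coupled_dataset):
    ds = coupled_dataset
    epochs = tf.epoch_trials(ds.recording, ds.events, None, "onset",
                             (-1.0, 1.0))
    px = tf.extract_phase(epochs, "NC1")
    py = tf.extract_phase(epochs, "HC1")
    return px, py


@pytest.fixture(scope="session")
def small_session():
    """Multichannel session with a planted lure+ power gain."""
    cfg = tf.SimConfig(n_trials_per_condition=8,
                       conditions=("lure+", "lure-"),
                       power_gain={"lure+": 1.5, "lure-": 1.0},
                       seed=7)
    return tf.simulate_session(cfg, n_nc=2, n_hc=2)
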