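"""Generate a synthetic session, write it to disk, and read it back.

Builds a multichannel session with neocortical and hippocampal channel
groups, condition labels, line noise and 1/f background, writes it as
EDF + tab-separated tables + a ground-truth sidecar, and prints the
behavioral accuracy summary.  The printed percentages are per stimulus
category (a lure trial counts as correct when answered "new").
"""

import tempfile
from pathlib import Path

import thetaflow as tf

cfg = tf.SimConfig(n_trials_per_condition=10,
                   conditions=("repeat+", "lure+", "lure-", "new+"),
                   seed=1)
ds = tf.simulate_session(cfg, n_nc=2, n_hc=2)
print(f"recording: {ds.recording.duration:.1f} s x "
      f"{ds.recording.n_channels} channels at {ds.recording.sfreq:g} Hz")

out = Path(tempfile.mkdtemp()) / "session"
files = tf.write_dataset(ds, out)
rec = tf.read_recording(files["recording"], channels=files["channels"])
print(f"EDF round-trip: {rec.n_channels} channels, "
      f"{rec.n_times} samples recovered")

truth = tf.read_truth(files["truth"])
print("ground truth for lure+:", truth["lure+"])

behavior = tf.summarize_behavior(tf.read_events(files["events"]))
for key, val in behavior.items():
    if key != "n_trials":
        print(f"accuracy {key}: {val:.1f}%")
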