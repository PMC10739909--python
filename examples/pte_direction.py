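"""Recover a planted direction of information flow with normalized PTE.

Simulates a neocortical-hippocampal channel pair with Kuramoto-style
NC->HC phase coupling (kappa = 0.8) at a 100 ms lag, extracts 4-5 Hz
instantaneous phase, and computes raw and normalized phase transfer
entropy plus the sender trial-exchange surrogate test.  A positive
normalized value indicates a net NC->HC bias; the surrogate p-value
tells whether it beats chance.
"""

import thetaflow as tf

cfg = tf.SimConfig(n_trials_per_condition=15, coupling_strength=0.8,
                   coupling_direction="nc->hc", seed=42)
ds = tf.simulate_coupled_pair(cfg)
epochs = tf.epoch_trials(ds.recording, ds.events, None, "onset",
                         (-1.0, 1.0))
px = tf.extract_phase(epochs, "NC1", band=(4.0, 5.0))
py = tf.extract_phase(epochs, "HC1", band=(4.0, 5.0))

params = tf.PTEParams(lag_s=0.1, window=(0.0, 1.0))
res = tf.pte_pair(px, py, params)
print(f"raw PTE NC->HC: {res['pte_xy_bits']:.4f} bits")
print(f"raw PTE HC->NC: {res['pte_yx_bits']:.4f} bits")
print(f"normalized PTE: {res['pte_norm']:+.4f} "
      "(positive = net NC->HC, matching the planted direction)")

null = tf.surrogate_null([(px, py)], params, n_iter=1000, seed=0)
print(f"surrogate test: observed {null.observed:+.4f}, "
      f"p = {null.p_value:.3f} over {null.n_iter} sender shuffles")

print("lag robustness (sign should be stable):")
for lag in (0.06, 0.08, 0.10, 0.12, 0.14):
    v = tf.pte_pair(px, py, tf.PTEParams(lag_s=lag,
                                         window=(0.0, 1.0)))["pte_norm"]
    print(f"  tau = {1000*lag:3.0f} ms -> {v:+.4f}")
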