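"""Preprocess one recording into network epochs and inspect the CNN.

Shows the raw-to-input transformation (26 channels @ 500 Hz -> 40 epochs
of 256 samples x 24 channels @ 128 Hz, band-passed 0.5-25 Hz) and the
architecture's shape arithmetic and parameter count.
"""

import eegsex as e

rec = e.generate_recording(e.EffectSpec(), sex=1, seed=7, duration_s=120.0)
print(f"raw recording: {rec.signal.shape[0]} channels x "
      f"{rec.signal.shape[1]} samples @ {rec.fs:.0f} Hz")

epochs = e.preprocess_recording(rec)
print(f"network input: {epochs.n_epochs} epochs of "
      f"{epochs.epochs.shape[1]} samples x {epochs.epochs.shape[2]} channels "
      f"@ {epochs.fs:.0f} Hz")

spec = e.default_archspec()
print(f"full-width architecture: {e.count_parameters(spec):,} trainable "
      "parameters (conv stack 1,021,900 + dense head 9,602)")

scaled = e.default_archspec(filter_scale=0.25)
print(f"quarter-width variant used for desk-scale runs: "
      f"{e.count_parameters(scaled):,} parameters")

net = e.build_network(scaled, seed=0)
proba = net.predict_proba(epochs.epochs[:5])
print("untrained per-epoch male probabilities:",
      [round(float(p), 3) for p in proba[:, 1]],
      "(near 0.5: the network has not learned anything yet)")
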