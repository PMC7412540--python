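"""Choosing the input window length.

Accuracy grows with window length but so does recognition latency, so the
window is chosen by maximizing the index I = Acc / (1 + Len/Con).  Here the
accuracy-vs-length curve is simulated with the saturating shape such sweeps
produce in practice; on real data the curve would come from training a
classifier per candidate length.
"""

import numpy as np

from evifuse import evaluation_index, select_window_length
from evifuse.windowing import WindowConfig

lengths = np.arange(1, 151)
accuracy = 0.95 * (1.0 - np.exp(-lengths / 8.0))  # saturates near 95%

cfg = WindowConfig(con=1000.0, poly_order=13)
best, poly = select_window_length(list(zip(lengths, accuracy)), cfg)

print(f"accuracy at 150 samples : {accuracy[-1]:.4f}")
print(f"index at 150 samples    : {evaluation_index(accuracy[-1], 150, cfg.con):.4f}")
print(f"selected window length  : {best} samples ({best / 50.0:.2f} s at 50 Hz)")
print(f"index at selected length: {evaluation_index(accuracy[best - 1], best, cfg.con):.4f}")
# The selected length sits where the curve has essentially saturated: longer
# windows add latency but almost no accuracy, shorter ones give up accuracy.
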