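"""Training the parallel one-vs-rest LSTM evidence bank.

Two clearly separable activities (a walking-like oscillation and a static
posture) are synthesized, windowed, and used to train one small two-layer
LSTM + softmax classifier per activity.  Each classifier answers only "is
this my activity or not", using the two-dimensional one-hot coding with a
shared complement class.  The stacked softmax outputs form the evidence
matrix the fusion stages consume.
"""

import numpy as np

import evifuse as ev
from evifuse.windowing import WindowConfig, slide_windows

profiles = [
    ev.ActivityProfile("walking", (0.0,) * 6, dynamic=True, amplitude=1.0,
                       frequency=2.0, noise_sd=0.2),
    ev.ActivityProfile("sitting", (0.6, 0.2, 0.8, 0.0, 0.0, 0.0), noise_sd=0.2),
]
rng = np.random.default_rng(0)
schedule = [(int(a), 4.0) for a in rng.integers(1, 3, 30)]
signal = ev.generate_signals(profiles, schedule, seed=1)
windows = slide_windows(signal, WindowConfig(length=20, overlap=0.5))
print(f"{windows.n_windows} windows of 20 samples (0.4 s at 50 Hz), 6 channels")

frame = ev.ActivityFrame(["walking", "sitting"])
specs = [ev.SubnetworkSpec(input_dim=6, hidden1=6, hidden2=6, output_dim=3)] * 2
print(f"weights per subnetwork: {ev.count_weights(specs[0])}")

bank = ev.train_subnetwork_bank(
    windows, frame, specs, learning_rate=0.3, batch_size=128, epochs=30,
    seed=0, standardize=True,
)

matrix = ev.emit_evidence(bank, windows.windows[0])
print(f"evidence matrix for a '{frame.names[windows.labels[0] - 1]}' window:")
print(np.round(matrix.values, 3))
# Row i is classifier i's probability vector over (walking, sitting,
# complement); a confident classifier puts its mass on its own column when
# the window is its activity and on the complement column otherwise.
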