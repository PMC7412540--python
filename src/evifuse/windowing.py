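"""Sliding-window segmentation of labeled inertial streams and the
accuracy-vs-latency index used to pick the window length.

Raw wearable-sensor recordings arrive as a ``T x C`` matrix of samples at a
fixed rate (the canonical setting is 6 channels — triaxial accelerometer and
gyroscope — at 50 Hz) with one integer activity label per sample.  Windows of
a fixed length, usually with 50% overlap between neighbours, are the basic
classification unit.

Because recognition latency grows with window length while accuracy
saturates, the window length is chosen by maximizing the evaluation index

    I(Len) = Acc(Len) / (1 + Len / Con)

where ``Con`` is a constant much larger than the longest candidate length.
A high-order polynomial is least-squares fitted to the index samples and the
fitted curve is maximized on a dense grid over the swept range.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "WindowConfig",
    "WindowSet",
    "slide_windows",
    "evaluation_index",
    "select_window_length",
    "read_inertial_signals",
    "read_signal_csv",
]


@dataclasses.dataclass
class SignalRecord:
    """A labeled multichannel time series.

    Attributes
    ----------
    samples : (T, C) float array of sensor readings.
    rate : sampling frequency in Hz.
    labels : (T,) int array of activity ids in ``1..n``.
    subject : optional subject identifier.
    """

    samples: np.ndarray
    rate: float
    labels: np.ndarray
    subject: str | None = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.samples.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"labels length {self.labels.shape[0]} != number of samples "
                f"{self.samples.shape[0]}"
            )
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValueError("signal must have at least one sample and one channel")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclasses.dataclass
class WindowConfig:
    """Window length in samples, overlap fraction, and index-fit settings."""

    length: int = 20
    overlap: float = 0.5
    con: float = 1000.0
    poly_order: int = 13

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("window length must be >= 1 sample")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        if self.con <= 0:
            raise ValueError("index constant con must be positive")

    @property
    def step(self) -> int:
        return max(1, int(round(self.length * (1.0 - self.overlap))))


@dataclasses.dataclass
class WindowSet:
    """Segmented windows: ``(N, length, C)`` array with one label per window."""

    windows: np.ndarray
    labels: np.ndarray
    step: int

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def _majority_label(chunk: np.ndarray) -> int:
    """Majority vote; ties go to the activity occurring earliest in the chunk."""
    values, first_pos = np.unique(chunk, return_index=True)
    counts = np.array([(chunk == v).sum() for v in values])
    best = counts == counts.max()
    return int(values[best][np.argmin(first_pos[best])])


def slide_windows(
    signal: SignalRecord, config: WindowConfig, drop_mixed: bool = False
) -> WindowSet:
    """Cut ``signal`` into overlapping fixed-length windows.

    The window label is the majority per-sample label (ties resolved to the
    activity appearing first within the window).  With ``drop_mixed=True``
    windows containing more than one activity are discarded instead.
    """
    L, step = config.length, config.step
    T = signal.n_samples
    if T < L:
        raise ValueError(
            f"signal has {T} samples but one window requires {L}; "
            "provide a longer signal or a shorter window"
        )
    starts = np.arange(0, T - L + 1, step)
    windows = np.stack([signal.samples[s : s + L] for s in starts])
    label_chunks = [signal.labels[s : s + L] for s in starts]
    if drop_mixed:
        keep = np.array([len(np.unique(c)) == 1 for c in label_chunks])
        windows = windows[keep]
        labels = np.array([c[0] for c, k in zip(label_chunks, keep) if k], dtype=np.int64)
    else:
        labels = np.array([_majority_label(c) for c in label_chunks], dtype=np.int64)
    return WindowSet(windows=windows, labels=labels, step=step)


def evaluation_index(acc, length, con: float):
    """Accuracy/latency tradeoff index ``acc / (1 + length/con)``.

    Increases with accuracy, decreases with window length; ``con`` is a
    constant much larger than the longest candidate length, which keeps the
    denominator near 1 and prevents short lengths from dominating outright.
    Accepts scalars or arrays.
    """
    if con <= 0:
        raise ValueError("con must be positive")
    length = np.asarray(length, dtype=np.float64)
    if np.any(length < 0):
        raise ValueError("window length must be nonnegative")
    return np.asarray(acc, dtype=np.float64) / (1.0 + length / con)


def select_window_length(
    curve: Sequence[tuple[float, float]], config: WindowConfig | None = None
) -> tuple[int, np.polynomial.Polynomial]:
    """Pick the window length maximizing the fitted evaluation index.

    Parameters
    ----------
    curve : sequence of ``(length, accuracy)`` pairs from a length sweep.
    config : supplies ``con`` and ``poly_order``.

    Returns the best integer length within the swept range and the fitted
    polynomial (callable on lengths).  The fitted curve is evaluated on a
    1-sample grid over the swept range; the argmax decides.
    """
    config = config or WindowConfig()
    pts = np.asarray(curve, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("curve must be a sequence of (length, accuracy) pairs")
    lengths, accs = pts[:, 0], pts[:, 1]
    if len(np.unique(lengths)) < config.poly_order + 1:
        raise ValueError(
            f"need at least poly_order+1={config.poly_order + 1} distinct lengths "
            f"to fit order {config.poly_order}; lower poly_order"
        )
    index = evaluation_index(accs, lengths, config.con)
    poly = np.polynomial.Polynomial.fit(lengths, index, deg=config.poly_order)
    grid = np.arange(int(np.min(lengths)), int(np.max(lengths)) + 1)
    best = int(grid[np.argmax(poly(grid))])
    return best, poly


# -- readers -------------------------------------------------------------


def read_inertial_signals(
    signal_paths: Sequence[str | Path], label_path: str | Path, rate: float = 50.0
) -> WindowSet:
    """Read the pre-windowed inertial-signals text layout.

    Each file in ``signal_paths`` holds one channel: a whitespace-delimited
    matrix with one row per window.  ``label_path`` holds one integer label
    per row.  Returns the stacked ``(N, length, C)`` window set (step is
    reported as half the window length, the layout's 50%-overlap convention).
    """
    channels = [np.loadtxt(p, dtype=np.float64, ndmin=2) for p in signal_paths]
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ValueError(f"channel files disagree in shape: {sorted(shapes)}")
    windows = np.stack(channels, axis=-1)  # (N, length, C)
    labels = np.loadtxt(label_path, dtype=np.int64, ndmin=1)
    if labels.shape[0] != windows.shape[0]:
        raise ValueError(
            f"{labels.shape[0]} labels for {windows.shape[0]} windows"
        )
    return WindowSet(windows=windows, labels=labels, step=max(1, windows.shape[1] // 2))


def read_signal_csv(path: str | Path, rate: float = 50.0) -> SignalRecord:
    """Read a long-format CSV stream: a ``time`` column, one column per
    channel, and a trailing integer ``label`` column."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c not in ("time", "label")]
    if "label" not in df.columns or not cols:
        raise ValueError("CSV must contain channel columns and a 'label' column")
    return SignalRecord(
        samples=df[cols].to_numpy(dtype=np.float64),
        rate=rate,
        labels=df["label"].to_numpy(dtype=np.int64),
    )
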