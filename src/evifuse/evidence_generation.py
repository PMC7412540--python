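"""Parallel one-vs-rest LSTM evidence bank.

One small two-layer LSTM + softmax subnetwork per activity.  Classifier s_i
is trained to separate its own activity a_i from everything else under a
two-dimensional one-hot coding: the target for a window of activity j is the
unit vector at position j when j = i, and the unit vector at the appended
complement position n+1 otherwise.  The bank's stacked softmax outputs form
the n x (n+1) evidence matrix E_t for each window — the raw evidence the
revision and combination stages consume.

Subnetworks are deliberately small (hidden sizes in the teens); the point of
the parallel design is that n tiny networks match one large one at a
comparable weight budget while remaining independently trainable and
executable.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .evidence_theory import ActivityFrame
from .windowing import WindowSet

__all__ = [
    "SubnetworkSpec",
    "EvidenceMatrix",
    "LSTMSubnetwork",
    "EvidenceBank",
    "encode_label",
    "build_subnetwork",
    "train_subnetwork_bank",
    "emit_evidence",
    "count_weights",
]

logger = logging.getLogger(__name__)

# Hidden sizes matching the reference selection: 16 for the three dynamic
# activities' classifiers, 20/20/6 for the three postural ones.
DEFAULT_HIDDEN_SIZES = (16, 16, 16, 20, 20, 6)


@dataclasses.dataclass(frozen=True)
class SubnetworkSpec:
    """Dimensions of one LSTM subnetwork: input channels, the two hidden
    layer widths, and the (n+1)-way softmax output."""

    input_dim: int
    hidden1: int
    hidden2: int
    output_dim: int

    def __post_init__(self):
        for name in dataclasses.fields(self):
            if getattr(self, name.name) < 1:
                raise ValueError(f"{name.name} must be >= 1")


@dataclasses.dataclass
class EvidenceMatrix:
    """n x (n+1) stacked softmax outputs for one window; each row is
    classifier s_i's probability vector (activities 1..n plus complement)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != v.shape[0] + 1:
            raise ValueError(f"expected (n, n+1) matrix, got {v.shape}")
        if np.any(v < 0):
            raise ValueError("evidence entries must be nonnegative")
        if np.any(np.abs(v.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("every evidence row must sum to 1")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def encode_label(activity: int, classifier: int, frame: ActivityFrame) -> np.ndarray:
    """Two-dimensional one-hot target for classifier ``classifier`` on a
    window of ``activity``: unit vector at the activity's position when the
    window is the classifier's own activity, else at the complement position
    n+1."""
    n = frame.n
    if not (1 <= activity <= n and 1 <= classifier <= n):
        raise ValueError(f"activity/classifier index outside 1..{n}")
    z = np.zeros(n + 1)
    z[activity - 1 if activity == classifier else n] = 1.0
    return z


def count_weights(spec: SubnetworkSpec) -> int:
    """Number of trainable weights (biases excluded) in a two-layer LSTM
    with a dense softmax head:

        4*((N_in + N_h1)*N_h1 + (N_h1 + N_h2)*N_h2) + N_h2*N_out

    The factor 4 counts the input/forget/cell/output gates.
    """
    c, h1, h2, out = spec.input_dim, spec.hidden1, spec.hidden2, spec.output_dim
    return 4 * ((c + h1) * h1 + (h1 + h2) * h2) + h2 * out


class LSTMSubnetwork:
    """Two-layer LSTM followed by a softmax classifier, trained by
    mini-batch gradient descent on cross entropy."""

    def __init__(self, spec: SubnetworkSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.params: dict[str, Tensor] = {}
        for layer, (din, h) in enumerate(
            [(spec.input_dim, spec.hidden1), (spec.hidden1, spec.hidden2)], start=1
        ):
            k = 1.0 / np.sqrt(h)
            self.params[f"Wx{layer}"] = self._param(rng.uniform(-k, k, (din, 4 * h)))
            self.params[f"Wh{layer}"] = self._param(rng.uniform(-k, k, (h, 4 * h)))
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias starts open
            self.params[f"b{layer}"] = self._param(b)
        k = 1.0 / np.sqrt(spec.hidden2)
        self.params["Wo"] = self._param(rng.uniform(-k, k, (spec.hidden2, spec.output_dim)))
        self.params["bo"] = self._param(np.zeros(spec.output_dim))

    @staticmethod
    def _param(value: np.ndarray) -> Tensor:
        return Tensor(value, requires_grad=True)

    def _zero_grads(self) -> None:
        for p in self.params.values():
            p.grad = None

    def _forward_graph(self, x: np.ndarray) -> Tensor:
        """Build the graph from a (B, T, C) batch to (B, n+1) probabilities."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[2] != self.spec.input_dim:
            raise ValueError(
                f"window has {x.shape[2]} channels, subnetwork expects {self.spec.input_dim}"
            )
        B, T, _ = x.shape
        h_in: list[Tensor] = [Tensor(x[:, t, :]) for t in range(T)]
        for layer, H in enumerate([self.spec.hidden1, self.spec.hidden2], start=1):
            Wx, Wh, b = (self.params[f"{k}{layer}"] for k in ("Wx", "Wh", "b"))
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
            outs: list[Tensor] = []
            for xt in h_in:
                z = xt @ Wx + h @ Wh + b
                i = ad.sigmoid(z[:, 0:H])
                f = ad.sigmoid(z[:, H : 2 * H])
                g = ad.tanh(z[:, 2 * H : 3 * H])
                o = ad.sigmoid(z[:, 3 * H : 4 * H])
                c = f * c + i * g
                h = o * ad.tanh(c)
                outs.append(h)
            h_in = outs
        logits = h_in[-1] @ self.params["Wo"] + self.params["bo"]
        shifted = logits - Tensor(logits.value.max(axis=1, keepdims=True))
        e = ad.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Softmax probabilities, (B, n+1) for a batch or (n+1,) for one
        (length, C) window."""
        single = np.asarray(x).ndim == 2
        probs = self._forward_graph(x).value
        return probs[0] if single else probs

    def train(
        self,
        windows: np.ndarray,
        targets: np.ndarray,
        learning_rate: float = 0.002,
        batch_size: int = 500,
        epochs: int = 200,
        seed: int | None = None,
        log_path: str | Path | None = None,
    ) -> pd.DataFrame:
        """Mini-batch gradient descent on cross entropy.

        ``targets`` is the (N, n+1) matrix of two-dimensional one-hot labels.
        Returns a per-epoch log (mean loss, training accuracy); also written
        to ``log_path`` as CSV when given.
        """
        windows = np.asarray(windows, dtype=np.float64)
        targets = np.asarray(targets, dtype=np.float64)
        if len(windows) == 0:
            raise ValueError("no training windows")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        N = len(windows)
        history = []
        for epoch in range(epochs):
            order = rng.permutation(N)
            losses = []
            for start in range(0, N, batch_size):
                idx = order[start : start + batch_size]
                probs = self._forward_graph(windows[idx])
                safe = ad.clamp_min(probs, 1e-12)
                loss = -(Tensor(targets[idx]) * ad.log(safe)).sum() * (1.0 / len(idx))
                self._zero_grads()
                loss.backward()
                for p in self.params.values():
                    p.value = p.value - learning_rate * p.grad
                losses.append(float(loss.value))
            probs = self.forward(windows)
            acc = float(np.mean(np.argmax(probs, axis=1) == np.argmax(targets, axis=1)))
            history.append({"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": acc})
            logger.debug("epoch %d loss %.4f acc %.4f", epoch, history[-1]["loss"], acc)
        df = pd.DataFrame(history)
        if log_path is not None:
            df.to_csv(log_path, index=False)
        return df


def build_subnetwork(spec: SubnetworkSpec, seed: int) -> LSTMSubnetwork:
    """Construct a seed-deterministic subnetwork (same seed, same initial
    parameters)."""
    return LSTMSubnetwork(spec, seed)


class EvidenceBank:
    """The n parallel one-vs-rest subnetworks plus their activity frame.

    When trained with standardization, the per-channel location/scale are
    stored so inference normalizes incoming windows identically.
    """

    def __init__(
        self,
        frame: ActivityFrame,
        subnetworks: Sequence[LSTMSubnetwork],
        norm: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        if len(subnetworks) != frame.n:
            raise ValueError(f"need {frame.n} subnetworks, got {len(subnetworks)}")
        self.frame = frame
        self.subnetworks = list(subnetworks)
        self.norm = norm

    def _normalize(self, windows: np.ndarray) -> np.ndarray:
        if self.norm is None:
            return windows
        mu, sd = self.norm
        return (windows - mu) / sd

    def total_weights(self) -> int:
        return sum(count_weights(s.spec) for s in self.subnetworks)

    def evidence_batch(self, windows: np.ndarray) -> np.ndarray:
        """(B, n, n+1) stacked evidence for a batch of windows.  Rows are
        produced by independent subnetworks, so row i for a window never
        depends on any other subnetwork (the parallel contract)."""
        windows = self._normalize(np.asarray(windows, dtype=np.float64))
        per_classifier = [s.forward(windows) for s in self.subnetworks]
        return np.stack(per_classifier, axis=1)

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {"n": np.array(self.frame.n)}
        if self.norm is not None:
            arrays["norm_mu"], arrays["norm_sd"] = self.norm
        for i, sub in enumerate(self.subnetworks):
            arrays[f"spec{i}"] = np.array(dataclasses.astuple(sub.spec))
            arrays[f"seed{i}"] = np.array(sub.seed)
            for name, p in sub.params.items():
                arrays[f"p{i}_{name}"] = p.value
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path, frame: ActivityFrame | None = None) -> "EvidenceBank":
        data = np.load(path)
        n = int(data["n"])
        frame = frame or ActivityFrame(n)
        subs = []
        for i in range(n):
            spec = SubnetworkSpec(*map(int, data[f"spec{i}"]))
            sub = LSTMSubnetwork(spec, int(data[f"seed{i}"]))
            for name in sub.params:
                sub.params[name] = Tensor(data[f"p{i}_{name}"], requires_grad=True)
            subs.append(sub)
        norm = (data["norm_mu"], data["norm_sd"]) if "norm_mu" in data else None
        return cls(frame, subs, norm=norm)


def train_subnetwork_bank(
    data: WindowSet,
    frame: ActivityFrame,
    specs: Sequence[SubnetworkSpec] | None = None,
    learning_rate: float = 0.002,
    batch_size: int = 500,
    epochs: int = 200,
    seed: int = 0,
    standardize: bool = False,
) -> EvidenceBank:
    """Train one subnetwork per activity on its two-dimensional one-hot
    targets.  ``specs`` defaults to the reference hidden sizes; seeds are
    derived deterministically from ``seed`` per classifier."""
    if data.n_windows == 0:
        raise ValueError("empty window set")
    labels = np.asarray(data.labels)
    if labels.min() < 1 or labels.max() > frame.n:
        raise ValueError(f"window labels must lie in 1..{frame.n}")
    C = data.windows.shape[2]
    if specs is None:
        sizes = DEFAULT_HIDDEN_SIZES[: frame.n]
        if len(sizes) < frame.n:
            sizes = sizes + (16,) * (frame.n - len(sizes))
        specs = [SubnetworkSpec(C, h, h, frame.n + 1) for h in sizes]
    if len(specs) != frame.n:
        raise ValueError(f"need one spec per activity ({frame.n}), got {len(specs)}")
    windows = data.windows
    norm = None
    if standardize:
        mu = windows.mean(axis=(0, 1))
        sd = windows.std(axis=(0, 1)) + 1e-12
        windows = (windows - mu) / sd
        norm = (mu, sd)  # (C,) each; broadcasts over single windows and batches
    subs = []
    for i, spec in enumerate(specs, start=1):
        sub = build_subnetwork(spec, seed=seed * 1000 + i)
        targets = np.stack([encode_label(int(lab), i, frame) for lab in labels])
        log = sub.train(
            windows, targets, learning_rate=learning_rate, batch_size=batch_size,
            epochs=epochs, seed=seed * 1000 + i,
        )
        logger.info(
            "classifier %d: final loss %.4f acc %.4f", i,
            log["loss"].iloc[-1], log["accuracy"].iloc[-1],
        )
        subs.append(sub)
    return EvidenceBank(frame, subs, norm=norm)


def emit_evidence(bank: EvidenceBank, window: np.ndarray) -> EvidenceMatrix:
    """Stack every subnetwork's softmax vector for one (length, C) window
    into the n x (n+1) evidence matrix."""
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2:
        raise ValueError("emit_evidence takes a single (length, C) window")
    window = bank._normalize(window)
    rows = [s.forward(window) for s in bank.subnetworks]
    return EvidenceMatrix(np.stack(rows))
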