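"""End-to-end orchestration of the stacked recognizer.

Glue between the stages: train the one-vs-rest bank, measure per-classifier
reliability on held-out windows, revise the bank's evidence, train the
combination weights, and evaluate fusion variants.  Each step is a thin
composition of the stage modules so any intermediate can be inspected or
replaced (e.g. a synthetic evidence stream in place of a trained bank).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .evidence_generation import EvidenceBank
from .evidence_theory import ActivityFrame
from .reliability import ConfusionCounts, judge_positive, reliability_matrix, tally_confusion
from .ts_combination import CombinationWeights, CombinerConfig, predict_stream, train_combiner
from .windowing import WindowSet

__all__ = [
    "fit_reliability",
    "revised_stream",
    "evaluate_predictions",
]


def fit_reliability(
    bank: EvidenceBank, windows: WindowSet
) -> tuple[list[ConfusionCounts], np.ndarray]:
    """Tally each classifier's one-vs-rest confusion on a window set and
    compute the reliability matrix P.  Meant to be run on held-out (test)
    windows so the coefficients measure generalization, not fit."""
    evidence = bank.evidence_batch(windows.windows)  # (B, n, n+1)
    n = bank.frame.n
    counts = [
        tally_confusion(judge_positive(evidence[:, i - 1, :], i), windows.labels, i)
        for i in range(1, n + 1)
    ]
    return counts, reliability_matrix(counts, n)


def revised_stream(bank: EvidenceBank, windows: WindowSet, p: np.ndarray) -> np.ndarray:
    """Revise the bank's evidence for every window: (B, n, n+2) stream of
    [E ⊙ P | Ω] rows, in window order (the stream's time axis)."""
    e = bank.evidence_batch(windows.windows)
    p = np.asarray(p, dtype=np.float64)
    revised = e * p[None]
    omega = np.sum(e * (1.0 - p[None]), axis=2, keepdims=True)
    return np.concatenate([revised, omega], axis=2)


def evaluate_predictions(
    predictions: np.ndarray, labels: np.ndarray, n: int
) -> dict:
    """Accuracy and confusion matrix as a JSON-serializable report."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    conf = np.zeros((n, n), dtype=int)
    for t, p in zip(labels, predictions):
        conf[t - 1, p - 1] += 1
    return {
        "accuracy": float(np.mean(predictions == labels)),
        "n_windows": int(len(labels)),
        "confusion": conf.tolist(),
    }
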