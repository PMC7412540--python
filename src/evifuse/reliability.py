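"""Classifier reliability assessment and evidence revision.

Each one-vs-rest classifier's raw softmax output is only as trustworthy as
the classifier itself.  From a confusion tally (TP/FP/TN/FN under the
one-vs-rest reading) two reliability coefficients are computed per
classifier s_i:

    P_i     = TP / (TP + FP + FN)      — trust in mass placed on activity a_i
    P_{n+1} = TN / (TN + FN + FP)      — trust in mass placed on the complement

All other positions of the reliability vector are zero: the classifier was
never asked about those categories, so any stray mass there is pure noise.
Revision takes the Hadamard product of the evidence matrix with the
reliability vectors and books the discounted remainder of each row as an
explicit uncertainty mass:

    Ẽ = E ⊙ P,   Ω_i = Σ_j E_ij (1 − P_ij)

which conserves each row's unit mass by construction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "tally_confusion",
    "reliability_coefficients",
    "reliability_matrix",
    "revise_evidence",
    "export_reliability_table",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion tally for a single classifier."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def tally_confusion(
    predictions: Sequence[bool] | np.ndarray, truths: Sequence[int] | np.ndarray, i: int
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN for classifier ``i``.

    ``predictions`` are the classifier's binary judgements ("this window is
    my activity"); ``truths`` are the window labels.  Positive + correct is
    TP, positive + wrong FP, negative + correct TN, negative + wrong FN.
    """
    predictions = np.asarray(predictions, dtype=bool)
    truths = np.asarray(truths, dtype=np.int64)
    if predictions.shape != truths.shape:
        raise ValueError(
            f"{predictions.shape[0]} predictions vs {truths.shape[0]} truths"
        )
    is_i = truths == i
    return ConfusionCounts(
        tp=int(np.sum(predictions & is_i)),
        fp=int(np.sum(predictions & ~is_i)),
        tn=int(np.sum(~predictions & ~is_i)),
        fn=int(np.sum(~predictions & is_i)),
    )


def judge_positive(evidence_rows: np.ndarray, i: int) -> np.ndarray:
    """Binary judgement feeding the tally: argmax of classifier i's
    (n+1)-vector falls on position i."""
    evidence_rows = np.atleast_2d(evidence_rows)
    return np.argmax(evidence_rows, axis=-1) == i - 1


def reliability_coefficients(counts: ConfusionCounts, i: int, n: int) -> np.ndarray:
    """Length-(n+1) reliability vector for classifier ``i``.

    Position ``i`` holds TP/(TP+FP+FN) — the fraction of windows that were
    or should have been judged as a_i that were judged correctly; position
    ``n+1`` holds TN/(TN+FN+FP), the analogue for the complement side.  All
    other positions are 0.
    """
    if not 1 <= i <= n:
        raise ValueError(f"classifier index {i} outside 1..{n}")
    pos_den = counts.tp + counts.fp + counts.fn
    neg_den = counts.tn + counts.fn + counts.fp
    if pos_den == 0:
        raise ValueError("TP+FP+FN = 0: positive-side reliability undefined")
    if neg_den == 0:
        raise ValueError("TN+FN+FP = 0: negative-side reliability undefined")
    p = np.zeros(n + 1)
    p[i - 1] = counts.tp / pos_den
    p[n] = counts.tn / neg_den
    return p


def reliability_matrix(all_counts: Sequence[ConfusionCounts], n: int) -> np.ndarray:
    """Stack per-classifier reliability vectors into the n x (n+1) matrix P."""
    if len(all_counts) != n:
        raise ValueError(f"need {n} confusion tallies, got {len(all_counts)}")
    return np.stack(
        [reliability_coefficients(c, i, n) for i, c in enumerate(all_counts, start=1)]
    )


def revise_evidence(e: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Discount an evidence matrix by per-classifier reliability.

    Parameters
    ----------
    e : (n, n+1) evidence matrix, each row a probability vector.
    p : (n, n+1) reliability matrix (rows from `reliability_coefficients`).

    Returns the (n, n+2) revised matrix ``[E ⊙ P | Ω]`` where
    ``Ω_i = Σ_j E_ij (1 − P_ij)``.  Every output row sums to the input row's
    mass (1), asserted to 1e-9.
    """
    e = np.asarray(e, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if e.shape != p.shape or e.ndim != 2 or e.shape[1] != e.shape[0] + 1:
        raise ValueError(f"expected matching (n, n+1) matrices, got {e.shape} and {p.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("reliability entries must lie in [0, 1]")
    revised = e * p
    omega = np.sum(e * (1.0 - p), axis=1, keepdims=True)
    out = np.hstack([revised, omega])
    np.testing.assert_allclose(out.sum(axis=1), e.sum(axis=1), atol=1e-9)
    return out


def export_reliability_table(
    train_counts: Sequence[ConfusionCounts],
    test_counts: Sequence[ConfusionCounts],
    path: str | Path,
) -> pd.DataFrame:
    """Write the per-classifier evaluation table to CSV: TP/FP/TN/FN on train
    and test data, then the two coefficients (computed on test data,
    displayed at 4 decimals)."""
    n = len(test_counts)
    rows = []
    for i, (tr, te) in enumerate(zip(train_counts, test_counts), start=1):
        p = reliability_coefficients(te, i, n)
        rows.append(
            {
                "classifier": i,
                "train_TP": tr.tp, "train_FP": tr.fp, "train_TN": tr.tn, "train_FN": tr.fn,
                "test_TP": te.tp, "test_FP": te.fp, "test_TN": te.tn, "test_FN": te.fn,
                "P_i": round(float(p[i - 1]), 4),
                "P_n1": round(float(p[n]), 4),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
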