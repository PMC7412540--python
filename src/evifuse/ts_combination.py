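"""Trainable two-layer evidence combination network.

The stacked recognizer's decision layer fuses the revised evidence in two
stages, both built on Dempster's rule:

* **intra-classifier combination** — for classifier s_i, the revised rows of
  the last N_i + 1 time intervals are each discounted by a trainable weight
  vector and folded together, exploiting the persistence of activities over
  adjacent windows;
* **inter-classifier combination** — each classifier's time-synthesized BPA
  has its complement mass merged into the frame (keeping the fusion
  (n+1)-dimensional), is discounted by a trainable per-classifier weight,
  and is folded into the running result E_f, initialized vacuous.

Weights are reparameterized through a sigmoid, W = 1 / (1 + e^{-alpha}), so
gradient descent can never push them outside (0, 1); the last (uncertainty)
position of every weight vector is pinned at 1 because frame mass is what
*absorbs* discounts and must not itself be discounted.  Training minimizes
the cross entropy of E_f's singleton masses against the (zero-expanded)
one-hot label plus an L2 penalty on the mapped weights; gradients flow
through the full discount/combination computation via the autodiff core.

An optional threshold theta drops classifiers whose complement + uncertainty
mass exceeds it from the inter-classifier fold — their evidence opposes or
abstains rather than supports, so skipping them saves computation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .evidence_theory import (
    ActivityFrame,
    BPA,
    combine_many,
    dempster_combine,
    merge_complement,
    row_to_bpa,
)

__all__ = [
    "CombinerConfig",
    "CombinationWeights",
    "FinalEvidence",
    "discount_row",
    "intra_combine",
    "inter_combine",
    "combination_loss",
    "expanded_label",
    "train_combiner",
    "predict",
    "predict_stream",
]

DEFAULT_HISTORY = (2, 3, 3, 6, 6, 0)  # N_i: combination window size minus one
_EPS = 1e-12


@dataclasses.dataclass
class CombinerConfig:
    """Hyper-parameters of the combination network.

    ``history[i]`` is N_i, the number of past intervals classifier i+1 folds
    in on top of the current one.  ``theta`` (None = disabled) filters
    non-supportive classifiers from the inter-classifier stage.  ``lambda2``
    weights the L2 penalty on mapped weights.  ``per_position`` gives the
    target-activity and complement positions independent weights instead of
    the default shared value.
    """

    history: tuple[int, ...] = DEFAULT_HISTORY
    theta: float | None = None
    lambda2: float = 0.0015
    learning_rate: float = 0.5
    epochs: int = 150
    seed: int = 0
    per_position: bool = False
    val_fraction: float = 0.2

    def __post_init__(self):
        self.history = tuple(int(h) for h in self.history)
        if any(h < 0 for h in self.history):
            raise ValueError("history sizes N_i must be >= 0")
        if self.theta is not None and not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be >= 0")

    @property
    def n(self) -> int:
        return len(self.history)

    @property
    def max_history(self) -> int:
        return max(self.history)


class CombinationWeights:
    """Sigmoid-parameterized discount weights.

    ``alpha_intra`` has shape (n, max_N+1) — one parameter per classifier
    and time offset, shared by the two active positions — or (n, max_N+1, 2)
    in per-position mode.  ``alpha_inter`` has shape (n,).  Mapped weights
    are ``1 / (1 + exp(-alpha))``; entries beyond a classifier's own history
    length are present but unused.
    """

    def __init__(
        self,
        alpha_intra: np.ndarray,
        alpha_inter: np.ndarray,
        history: tuple[int, ...],
        per_position: bool = False,
    ):
        self.alpha_intra = np.asarray(alpha_intra, dtype=np.float64)
        self.alpha_inter = np.asarray(alpha_inter, dtype=np.float64)
        self.history = tuple(history)
        self.per_position = per_position
        n, d = len(history), max(history) + 1
        want = (n, d, 2) if per_position else (n, d)
        if self.alpha_intra.shape != want or self.alpha_inter.shape != (n,):
            raise ValueError(
                f"alpha shapes {self.alpha_intra.shape}/{self.alpha_inter.shape} "
                f"do not match history {history} (expected {want} and ({n},))"
            )

    @classmethod
    def zeros(cls, config: CombinerConfig) -> "CombinationWeights":
        """alpha = 0, i.e. all mapped weights 0.5 — the symmetric start."""
        n, d = config.n, config.max_history + 1
        shape = (n, d, 2) if config.per_position else (n, d)
        return cls(np.zeros(shape), np.zeros(n), config.history, config.per_position)

    @classmethod
    def unit(cls, history: Sequence[int], per_position: bool = False) -> "CombinationWeights":
        """Mapped weights exactly 1 (alpha = +inf): discounting disabled."""
        n, d = len(history), max(history) + 1
        shape = (n, d, 2) if per_position else (n, d)
        return cls(np.full(shape, np.inf), np.full(n, np.inf), tuple(history), per_position)

    def intra_weights(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.alpha_intra))

    def inter_weights(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.alpha_inter))


@dataclasses.dataclass
class FinalEvidence:
    """Result of the inter-classifier combination: a BPA over singletons plus
    the frame (merged regime) or the full powerset, with a flag raised when
    every classifier was filtered out and the result is vacuous."""

    bpa: BPA
    low_confidence: bool = False

    @property
    def frame(self) -> ActivityFrame:
        return self.bpa.frame


# ---------------------------------------------------------------------------
# reference per-window path (BPA objects; mirrors Algorithm 1 line by line)
# ---------------------------------------------------------------------------


def discount_row(row: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Discount one revised-evidence row by a weight vector.

    ``weights`` has length n+2 with entries in (0, 1] and the last entry
    pinned at 1.  Committed masses are scaled, the shaved-off mass joins the
    uncertainty column, and the row keeps its unit mass:

        Ê_j = Ẽ_j W_j (j <= n+1),   Ω̂ = Ω + Σ_j Ẽ_j (1 − W_j)
    """
    row = np.asarray(row, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if row.shape != weights.shape:
        raise ValueError(f"row {row.shape} vs weights {weights.shape}")
    if np.any(weights[:-1] <= 0) or np.any(weights[:-1] > 1):
        raise ValueError("active weights must lie in (0, 1]")
    if weights[-1] != 1.0:
        raise ValueError("uncertainty-position weight must be the constant 1")
    out = row * weights
    out[-1] = row[-1] + np.sum(row[:-1] * (1.0 - weights[:-1]))
    return out


def intra_combine(
    history: Sequence[np.ndarray],
    weights: np.ndarray,
    i: int,
    frame: ActivityFrame,
) -> BPA:
    """Fold classifier ``i``'s revised rows over its time window.

    ``history`` holds the N_i + 1 rows (most recent first or last — the fold
    is order-independent); ``weights`` is the matching (N_i+1, n+2) weight
    matrix.  Each row is discounted by its offset's weight vector, converted
    to a BPA, and Dempster-folded.  The output's focal elements stay within
    {a_i, complement, frame}: all inputs share that support, so combination
    only moves mass between those three.
    """
    history = [np.asarray(r, dtype=np.float64) for r in history]
    if not history:
        raise ValueError("intra-classifier history is empty")
    weights = np.atleast_2d(np.asarray(weights, dtype=np.float64))
    if weights.shape[0] != len(history):
        raise ValueError(f"{len(history)} rows but {weights.shape[0]} weight vectors")
    bpas = [
        row_to_bpa(discount_row(row, w), i, frame) for row, w in zip(history, weights)
    ]
    return combine_many(bpas)


def inter_combine(
    intra_results: Sequence[BPA],
    weights: np.ndarray,
    theta: float | None,
    frame: ActivityFrame,
    merger: bool = True,
) -> FinalEvidence:
    """Fuse the per-classifier synthesized BPAs into the final evidence E_f.

    E_f starts vacuous.  For each classifier i the complement mass is merged
    into the frame (merged regime), the support is discounted by the
    classifier's inter weight, and the result is Dempster-combined into E_f.
    With ``theta`` set, classifiers whose complement + frame mass exceeds it
    are skipped as non-supportive.  With ``merger=False`` the complement is
    kept as its own focal element (discounting still precedes combination)
    and E_f may develop up to 2^n − 1 focal elements.
    """
    if len(intra_results) != frame.n:
        raise ValueError(f"need one intra result per classifier ({frame.n})")
    weights = np.asarray(weights, dtype=np.float64)
    ef = BPA.vacuous(frame)
    used = 0
    for i, (bpa, w) in enumerate(zip(intra_results, weights), start=1):
        sing, comp, theta_fe = frame.singleton(i), frame.complement(i), frame.theta
        if theta is not None and bpa.mass(comp) + bpa.mass(theta_fe) > theta:
            continue
        if merger:
            b = merge_complement(bpa, i)
            s = b.mass(sing) * w
            b = BPA(frame, {sing: s, theta_fe: 1.0 - s})
        else:
            s, c = bpa.mass(sing) * w, bpa.mass(comp) * w
            b = BPA(frame, {sing: s, comp: c, theta_fe: 1.0 - s - c})
        ef = dempster_combine(ef, b)
        used += 1
    if used == 0:
        warnings.warn("all classifiers filtered by theta; final evidence is vacuous")
        return FinalEvidence(BPA.vacuous(frame), low_confidence=True)
    return FinalEvidence(ef, low_confidence=ef.is_vacuous)


def expanded_label(activity: int, frame: ActivityFrame, powerset: bool = False) -> np.ndarray:
    """One-hot label padded with zeros for the non-singleton focal positions:
    one extra zero (frame) in the merged regime, 2^n − 1 − n extras in the
    powerset regime."""
    n = frame.n
    if not 1 <= activity <= n:
        raise ValueError(f"activity {activity} outside 1..{n}")
    size = (2**n - 1) if powerset else (n + 1)
    z = np.zeros(size)
    z[activity - 1] = 1.0
    return z


def combination_loss(
    ef: FinalEvidence,
    label: int | np.ndarray,
    weights: CombinationWeights | None = None,
    lambda2: float = 0.0,
) -> float:
    """Regularized cross entropy of the final evidence.

    ``-Σ_j z_j ln E_f,j`` over the n singleton positions (the expanded
    label's extra positions are zero and contribute nothing), plus
    ``lambda2`` times the sum of squared mapped weights.  Singleton masses
    are clamped at 1e-12 so a zero mass yields a large finite loss.
    """
    frame = ef.frame
    z = (
        expanded_label(label, frame)[: frame.n]
        if np.isscalar(label)
        else np.asarray(label, dtype=np.float64)[: frame.n]
    )
    sing = np.maximum(ef.bpa.singleton_masses(), _EPS)
    loss = -float(np.sum(z * np.log(sing)))
    if weights is not None and lambda2 > 0:
        wi = weights.intra_weights()
        mask = _history_mask(weights.history, per_position=weights.per_position)
        loss += lambda2 * float(
            np.sum(weights.inter_weights() ** 2) + np.sum((wi * mask) ** 2)
        )
    return loss


def _history_mask(history: tuple[int, ...], per_position: bool) -> np.ndarray:
    """1 for (classifier, offset) slots inside the classifier's history."""
    n, d = len(history), max(history) + 1
    mask = (np.arange(d)[None, :] <= np.asarray(history)[:, None]).astype(float)
    return mask[..., None] * np.ones(2) if per_position else mask


def predict(ef: FinalEvidence) -> int:
    """Final activity: argmax over singleton masses, ties broken toward the
    lowest index; a vacuous E_f (all-zero singletons) yields activity 1 with
    ``ef.low_confidence`` set."""
    sing = ef.bpa.singleton_masses()
    if np.all(sing <= _EPS):
        ef.low_confidence = True
        return 1
    return int(np.argmax(sing)) + 1


# ---------------------------------------------------------------------------
# batched differentiable path (used for training, gradients, and fast eval)
# ---------------------------------------------------------------------------


def _gather_history(
    stream: np.ndarray, ts: np.ndarray, i: int, d: int, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row components of classifier ``i`` (0-based) at offset ``d`` before
    each index in ``ts``.  Indices before the stream start are padded with
    the vacuous row (0, 0, 1): Dempster-combining with it is the identity,
    so padding reproduces the shorter fold used at sequence start exactly."""
    idx = ts - d
    valid = idx >= 0
    safe = np.where(valid, idx, 0)
    s = np.where(valid, stream[safe, i, i], 0.0)
    c = np.where(valid, stream[safe, i, n], 0.0)
    u = np.where(valid, stream[safe, i, n + 1], 1.0)
    return s, c, u


def _forward_batch(
    stream: np.ndarray,
    ts: np.ndarray,
    a_intra: Tensor,
    a_inter: Tensor,
    config: CombinerConfig,
) -> tuple[list[Tensor], Tensor, np.ndarray]:
    """Differentiable merged-regime forward pass for a batch of intervals.

    Returns the n singleton-mass tensors and the frame-mass tensor of E_f
    (each shaped like ``ts``) plus a boolean matrix of theta-filter hits.
    """
    n = config.n
    m_sing: list[Tensor] = [Tensor(np.zeros(len(ts))) for _ in range(n)]
    m_theta: Tensor = Tensor(np.ones(len(ts)))
    filtered = np.zeros((n, len(ts)), dtype=bool)
    for i in range(n):
        # intra-classifier fold over the time window
        S, C, U = None, None, None
        for d in range(config.history[i] + 1):
            s_v, c_v, u_v = _gather_history(stream, ts, i, d, n)
            if config.per_position:
                ws, wc = ad.sigmoid(a_intra[i, d, 0]), ad.sigmoid(a_intra[i, d, 1])
            else:
                ws = wc = ad.sigmoid(a_intra[i, d])
            sh = Tensor(s_v) * ws
            ch = Tensor(c_v) * wc
            uh = 1.0 - sh - ch
            if S is None:
                S, C, U = sh, ch, uh
            else:
                K = S * ch + C * sh
                denom = ad.clamp_min(1.0 - K, _EPS)
                S, C, U = (
                    (S * sh + S * uh + U * sh) / denom,
                    (C * ch + C * uh + U * ch) / denom,
                    (U * uh) / denom,
                )
        # theta filter decides on the synthesized BPA's non-support mass
        if config.theta is not None:
            filtered[i] = (C.value + U.value) > config.theta
        # complement merger + inter discount -> simple support (sigma, 1-sigma)
        sigma = S * ad.sigmoid(a_inter[i])
        if config.theta is not None:
            sigma = sigma * Tensor((~filtered[i]).astype(float))
        # Dempster-combine the simple support into the running E_f
        others = None
        for j in range(n):
            if j != i:
                others = m_sing[j] if others is None else others + m_sing[j]
        K = sigma * others
        denom = ad.clamp_min(1.0 - K, _EPS)
        v = 1.0 - sigma
        new_sing = [
            (m_sing[j] + m_theta * sigma) / denom if j == i else (m_sing[j] * v) / denom
            for j in range(n)
        ]
        m_sing, m_theta = new_sing, (m_theta * v) / denom
    return m_sing, m_theta, filtered


def _batch_loss(
    stream: np.ndarray,
    labels: np.ndarray,
    ts: np.ndarray,
    a_intra: Tensor,
    a_inter: Tensor,
    config: CombinerConfig,
) -> Tensor:
    """Mean Eq.-10 loss over the batch: cross entropy of E_f's singleton
    masses against the expanded labels plus the L2 penalty on mapped
    weights (constant across the batch, added once)."""
    n = config.n
    m_sing, _, _ = _forward_batch(stream, ts, a_intra, a_inter, config)
    ce = None
    batch_labels = labels[ts]
    for j in range(n):
        zj = (batch_labels == j + 1).astype(float)
        term = Tensor(zj) * ad.log(ad.clamp_min(m_sing[j], _EPS))
        ce = term if ce is None else ce + term
    loss = -ce.mean()
    if config.lambda2 > 0:
        mask = _history_mask(config.history, config.per_position)
        wi = ad.sigmoid(a_intra) * Tensor(mask)
        wh = ad.sigmoid(a_inter)
        loss = loss + config.lambda2 * ((wi * wi).sum() + (wh * wh).sum())
    return loss


def combiner_gradient(
    stream: np.ndarray,
    labels: np.ndarray,
    weights: CombinationWeights,
    config: CombinerConfig,
    ts: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss and its gradient w.r.t. the alpha parameters, by reverse-mode
    differentiation through the full discount/combination computation."""
    stream = np.asarray(stream, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if ts is None:
        ts = np.arange(len(stream))
    a_intra = Tensor(weights.alpha_intra, requires_grad=True)
    a_inter = Tensor(weights.alpha_inter, requires_grad=True)
    loss = _batch_loss(stream, labels, np.asarray(ts), a_intra, a_inter, config)
    loss.backward()
    return float(loss.value), a_intra.grad.copy(), a_inter.grad.copy()


def train_combiner(
    stream: np.ndarray,
    labels: np.ndarray,
    config: CombinerConfig,
) -> CombinationWeights:
    """Learn the discount weights by full-batch gradient descent on the
    regularized cross entropy.

    ``stream`` is the (T, n, n+2) revised-evidence tensor, ``labels`` the
    per-interval truth.  A held-out fraction of intervals tracks validation
    loss; the weights from the best validation epoch are returned.
    """
    stream = np.asarray(stream, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n = config.n
    if stream.ndim != 3 or stream.shape[1] != n or stream.shape[2] != n + 2:
        raise ValueError(f"stream must be (T, {n}, {n + 2}), got {stream.shape}")
    if len(labels) != len(stream):
        raise ValueError("labels length must match stream length")
    if len(stream) <= config.max_history:
        raise ValueError(
            f"stream of {len(stream)} intervals is shorter than the largest "
            f"history window ({config.max_history + 1})"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(stream))
    n_val = max(1, int(len(stream) * config.val_fraction))
    val_ts, train_ts = order[:n_val], order[n_val:]

    weights = CombinationWeights.zeros(config)
    best = (np.inf, weights.alpha_intra.copy(), weights.alpha_inter.copy())
    for epoch in range(config.epochs):
        loss, g_intra, g_inter = combiner_gradient(stream, labels, weights, config, train_ts)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss ({loss}) at epoch {epoch}; "
                "check the evidence stream for invalid rows"
            )
        weights.alpha_intra -= config.learning_rate * g_intra
        weights.alpha_inter -= config.learning_rate * g_inter
        a_i = Tensor(weights.alpha_intra)
        a_e = Tensor(weights.alpha_inter)
        val_loss = float(_batch_loss(stream, labels, val_ts, a_i, a_e, config).value)
        if val_loss < best[0]:
            best = (val_loss, weights.alpha_intra.copy(), weights.alpha_inter.copy())
    return CombinationWeights(best[1], best[2], config.history, config.per_position)


def predict_stream(
    stream: np.ndarray,
    weights: CombinationWeights | None,
    config: CombinerConfig,
    mode: str = "intra+inter",
    merger: bool = True,
    return_masses: bool = False,
):
    """Predict an activity for every interval of a revised-evidence stream.

    ``mode`` selects the fusion depth: ``"maxout"`` takes the classifier
    with the largest own-activity mass (no combination), ``"inter"`` fuses
    the current interval's classifiers only (history forced to 0), and
    ``"intra+inter"`` runs the full two-layer combination.  ``weights=None``
    means unit weights (no discounting).  ``merger=False`` evaluates the
    full-powerset regime through the per-window reference path.
    """
    stream = np.asarray(stream, dtype=np.float64)
    n = config.n
    if mode == "maxout":
        preds = np.argmax(stream[:, np.arange(n), np.arange(n)], axis=1) + 1
        return (preds, None) if return_masses else preds
    if mode == "inter":
        config = dataclasses.replace(config, history=(0,) * n)
        if weights is not None:
            weights = CombinationWeights(
                weights.alpha_intra[:, :1] if not weights.per_position else weights.alpha_intra[:, :1, :],
                weights.alpha_inter,
                (0,) * n,
                weights.per_position,
            )
    elif mode != "intra+inter":
        raise ValueError(f"unknown mode {mode!r}")
    if weights is None:
        weights = CombinationWeights.unit(config.history, config.per_position)
    if not merger:
        return _predict_stream_powerset(stream, weights, config, return_masses)
    ts = np.arange(len(stream))
    a_i, a_e = Tensor(weights.alpha_intra), Tensor(weights.alpha_inter)
    m_sing, m_theta, filtered = _forward_batch(stream, ts, a_i, a_e, config)
    sing = np.stack([m.value for m in m_sing], axis=1)
    if config.theta is not None and filtered.all(axis=0).any():
        warnings.warn("some intervals had every classifier theta-filtered; vacuous E_f")
    preds = np.where(sing.max(axis=1) <= _EPS, 1, np.argmax(sing, axis=1) + 1)
    if return_masses:
        return preds, np.column_stack([sing, m_theta.value])
    return preds


def _predict_stream_powerset(
    stream: np.ndarray,
    weights: CombinationWeights,
    config: CombinerConfig,
    return_masses: bool,
):
    """Merger-off evaluation through the BPA-object reference path."""
    n = config.n
    frame = ActivityFrame(n)
    wi = weights.intra_weights()
    we = weights.inter_weights()
    preds = np.empty(len(stream), dtype=np.int64)
    all_sing = np.empty((len(stream), n))
    for t in range(len(stream)):
        intra = []
        for i in range(1, n + 1):
            hist, wrows = [], []
            for d in range(config.history[i - 1] + 1):
                if t - d < 0:
                    break
                hist.append(stream[t - d, i - 1])
                w = np.ones(n + 2)
                if config.per_position:
                    w[: n + 1] = wi[i - 1, d, 0]
                    w[n] = wi[i - 1, d, 1]
                else:
                    w[: n + 1] = wi[i - 1, d]
                wrows.append(w)
            intra.append(intra_combine(hist, np.stack(wrows), i, frame))
        ef = inter_combine(intra, we, config.theta, frame, merger=False)
        preds[t] = predict(ef)
        all_sing[t] = ef.bpa.singleton_masses()
    return (preds, all_sing) if return_masses else preds
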