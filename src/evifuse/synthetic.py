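"""Synthetic fixtures: IMU-like labeled signals and evidence streams.

Two generators make every stage testable without external data:

* :func:`generate_signals` emulates a 6-channel, 50 Hz body-worn
  accelerometer + gyroscope recording.  Dynamic activities (walking-like)
  are quasi-periodic sinusoids at activity-specific frequency and amplitude;
  static postures are constant channel offsets; both carry additive Gaussian
  noise.  A confusable posture pair (near-identical offsets, think sitting
  vs standing) reproduces the hardest aspect of real activity data.
* :func:`generate_evidence_stream` skips the signal and classifier stages
  and emits revised-evidence rows directly, with per-classifier accuracy
  levels, temporally correlated errors, targeted confusions, and optional
  label-independent "noise" classifiers — the controllable test bed for the
  combination network.

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence_theory import ActivityFrame
from .windowing import SignalRecord, WindowSet

__all__ = [
    "ActivityProfile",
    "EvidenceStreamSpec",
    "default_profiles",
    "generate_signals",
    "activity_bouts",
    "generate_evidence_stream",
    "write_inertial_signals",
    "write_signal_csv",
]


@dataclasses.dataclass(frozen=True)
class ActivityProfile:
    """How one activity looks on the sensor channels."""

    name: str
    means: tuple[float, ...]
    dynamic: bool = False
    amplitude: float = 0.0
    frequency: float = 0.0  # Hz; must stay below the Nyquist rate
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dynamic and self.frequency <= 0:
            raise ValueError("dynamic activities need a positive frequency")


def default_profiles(noise_sd: float = 0.3, channels: int = 6) -> list[ActivityProfile]:
    """Six activities mirroring the canonical protocol: three dynamic
    (walking, walking upstairs, walking downstairs — distinct gait
    frequencies and amplitudes) and three postures (sitting and standing
    nearly identical, lying clearly distinct)."""
    z = (0.0,) * channels
    base_sit = tuple([0.5, 0.1, 0.8] + [0.0] * (channels - 3))
    base_stand = tuple([0.55, 0.12, 0.82] + [0.0] * (channels - 3))  # confusable pair
    base_lie = tuple([0.9, -0.6, 0.1] + [0.0] * (channels - 3))
    return [
        ActivityProfile("walking", z, dynamic=True, amplitude=1.0, frequency=2.0, noise_sd=noise_sd),
        ActivityProfile("walking_up", z, dynamic=True, amplitude=0.8, frequency=1.4, noise_sd=noise_sd),
        ActivityProfile("walking_down", z, dynamic=True, amplitude=1.3, frequency=2.6, noise_sd=noise_sd),
        ActivityProfile("sitting", base_sit, noise_sd=noise_sd),
        ActivityProfile("standing", base_stand, noise_sd=noise_sd),
        ActivityProfile("lying", base_lie, noise_sd=noise_sd),
    ]


def generate_signals(
    profiles: Sequence[ActivityProfile],
    schedule: Sequence[tuple[int, float]],
    rate: float = 50.0,
    seed: int = 0,
) -> SignalRecord:
    """Synthesize a labeled multichannel recording.

    ``schedule`` is a sequence of (activity id, duration in seconds) bouts.
    Dynamic activities produce ``mean + amplitude * sin(2π f t + φ)`` per
    channel (random phase per bout and channel), postures produce their
    constant offsets; Gaussian noise is added throughout.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one bout")
    for p in profiles:
        if p.dynamic and p.frequency >= rate / 2:
            raise ValueError(
                f"profile {p.name!r}: frequency {p.frequency} Hz >= Nyquist ({rate / 2} Hz)"
            )
    rng = np.random.default_rng(seed)
    C = len(profiles[0].means)
    chunks, label_chunks = [], []
    for activity, duration in schedule:
        if not 1 <= activity <= len(profiles):
            raise ValueError(f"activity {activity} has no profile")
        p = profiles[activity - 1]
        T = int(round(duration * rate))
        t = np.arange(T) / rate
        x = np.tile(np.asarray(p.means), (T, 1))
        if p.dynamic:
            phases = rng.uniform(0, 2 * np.pi, C)
            x = x + p.amplitude * np.sin(2 * np.pi * p.frequency * t[:, None] + phases)
        if p.noise_sd > 0:
            x = x + rng.normal(0.0, p.noise_sd, (T, C))
        chunks.append(x)
        label_chunks.append(np.full(T, activity, dtype=np.int64))
    return SignalRecord(
        samples=np.vstack(chunks), rate=rate, labels=np.concatenate(label_chunks)
    )


def activity_bouts(
    n_windows: int, n_activities: int, bout_length: int = 100, seed: int = 0
) -> np.ndarray:
    """A random truth sequence of activity bouts, one label per interval.

    The default mean bout of 100 intervals corresponds to ~20 s of activity
    at the canonical granularity (0.4 s windows advanced by 0.2 s), the
    scale at which scripted daily-activity protocols switch activities.
    """
    rng = np.random.default_rng(seed)
    labels = np.empty(n_windows, dtype=np.int64)
    t = 0
    while t < n_windows:
        span = max(1, int(rng.poisson(bout_length)))
        labels[t : t + span] = rng.integers(1, n_activities + 1)
        t += span
    return labels


@dataclasses.dataclass(frozen=True)
class EvidenceStreamSpec:
    """Controls for the synthetic revised-evidence generator.

    ``accuracies[i]`` is classifier i+1's probability of a correct judgement
    on any interval; defaults mirror the quality pattern seen on real
    sensor data (dynamic activities well separated, one weak confusable
    posture pair, lying near-perfect).  Errors follow an AR(1) latent
    process with correlation length ``corr_length`` intervals.  A classifier
    in ``noise_classifiers`` ignores the truth entirely and flips a fair
    coin between support and rejection.  ``confusable`` maps a classifier to
    the activity its false positives concentrate on.
    """

    accuracies: tuple[float, ...] = (0.95, 0.95, 0.95, 0.78, 0.84, 0.99)
    corr_length: float = 2.0
    confusable: Mapping[int, int] = dataclasses.field(
        default_factory=lambda: {4: 5, 5: 4}
    )
    support_ranges: tuple[tuple[float, float], ...] | None = None
    noise_classifiers: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if any(not 0.0 <= a <= 1.0 for a in self.accuracies):
            raise ValueError("accuracy levels must lie in [0, 1]")

    def support_range(self, i: int) -> tuple[float, float]:
        """Support-mass range for classifier ``i`` (1-based).  The default
        makes the confusable pair overconfident: small one-vs-rest networks
        facing near-identical classes overfit and emit peaked softmax
        outputs whether they are right or wrong."""
        if self.support_ranges is not None:
            return self.support_ranges[i - 1]
        if i in self.confusable:
            return (0.80, 0.98)
        return (0.65, 0.95)


def _correlated_errors(rng, n: int, acc: float, corr_length: float) -> np.ndarray:
    """Boolean error indicators with marginal rate 1-acc and AR(1)
    autocorrelation exp(-1/corr_length) in the latent Gaussian."""
    rho = np.exp(-1.0 / corr_length) if corr_length > 0 else 0.0
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n) * np.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        z[t] = rho * z[t - 1] + innov[t]
    # error when latent exceeds the acc-quantile of N(0,1)
    from math import erf, sqrt

    phi = 0.5 * (1.0 + np.vectorize(erf)(z / np.sqrt(2.0)))
    return phi > acc


def generate_raw_evidence(
    spec: EvidenceStreamSpec, frame: ActivityFrame, truths: np.ndarray
) -> np.ndarray:
    """Emit a (T, n, n+1) raw evidence stream — stacked one-vs-rest softmax
    rows — for a truth sequence.

    A correct judgement by classifier i places strong mass on the right
    side (the own-activity column when the truth is a_i, the complement
    column otherwise); a wrong one places misleading or vacuous mass.  The
    leftover mass is spread over the remaining columns, as a softmax head
    would.  Rows sum to 1.
    """
    truths = np.asarray(truths, dtype=np.int64)
    n = frame.n
    if len(spec.accuracies) != n:
        raise ValueError(f"need {n} accuracy levels, got {len(spec.accuracies)}")
    T = len(truths)
    rng = np.random.default_rng(spec.seed)
    raw = np.zeros((T, n, n + 1))
    for i in range(1, n + 1):
        acc = spec.accuracies[i - 1]
        errors = _correlated_errors(rng, T, acc, spec.corr_length)
        if i in spec.noise_classifiers:
            support = rng.random(T) < 0.5  # coin flip, truth-independent
        else:
            partner = spec.confusable.get(i)
            fp_ok = (
                (truths == partner)
                if partner is not None
                else np.zeros(T, dtype=bool)
            )
            on_target = truths == i
            # off-target errors away from the confusable partner are rare
            stray = rng.random(T) < 0.2
            err = errors & (on_target | fp_ok | stray)
            support = np.where(on_target, ~err, err)
        lo, hi = spec.support_range(i)
        # false support is drawn from the same range as true support: a
        # confused classifier cannot tell its errors from its hits
        s_on = rng.uniform(lo, hi, T)
        c_hi = rng.uniform(0.65, 0.95, T)
        vac = rng.random(T) < 0.5  # wrong-but-hesitant vs wrong-and-assertive
        s = np.where(support, s_on, 0.02)
        c = np.where(support, 0.02, np.where(vac, 0.1, c_hi))
        if i in spec.noise_classifiers:
            s = np.where(support, rng.uniform(0.5, 0.9, T), 0.02)
        raw[:, i - 1, i - 1] = s
        raw[:, i - 1, n] = c
        # softmax leftovers on the other singleton columns (revision zeroes
        # them out, transferring the mass to uncertainty)
        rest = (1.0 - s - c) / (n - 1)
        for j in range(n):
            if j != i - 1:
                raw[:, i - 1, j] = rest
    return raw


def generate_evidence_stream(
    spec: EvidenceStreamSpec,
    frame: ActivityFrame,
    truths: np.ndarray,
    reliability: str = "measured",
    return_details: bool = False,
):
    """Revised-evidence stream for a truth sequence: (T, n, n+2) plus labels.

    With ``reliability="measured"`` (the default, matching the full
    pipeline) raw evidence from :func:`generate_raw_evidence` is passed
    through the actual reliability machinery: one-vs-rest judgements are
    tallied against the truth, coefficients computed, and the evidence
    revised — so the stream carries the same accuracy-reflecting discounts
    a trained bank's revised output would.  ``reliability="ideal"`` instead
    trusts every classifier fully (coefficients 1 at the two active
    positions), so only the off-target softmax leftovers move to the
    uncertainty column — the setting for experiments that must isolate what
    the *combiner's trainable weights* can discover about classifier
    quality.  With ``return_details=True`` the raw stream and the
    reliability matrix are returned as well.
    """
    from .reliability import judge_positive, reliability_matrix, tally_confusion

    truths = np.asarray(truths, dtype=np.int64)
    n = frame.n
    raw = generate_raw_evidence(spec, frame, truths)
    if reliability == "measured":
        counts = [
            tally_confusion(judge_positive(raw[:, i - 1, :], i), truths, i)
            for i in range(1, n + 1)
        ]
        p = reliability_matrix(counts, n)
    elif reliability == "ideal":
        p = np.zeros((n, n + 1))
        p[np.arange(n), np.arange(n)] = 1.0
        p[:, n] = 1.0
    else:
        raise ValueError("reliability must be 'measured' or 'ideal'")
    revised = raw * p[None]
    omega = np.sum(raw * (1.0 - p[None]), axis=2, keepdims=True)
    stream = np.concatenate([revised, omega], axis=2)
    if return_details:
        return stream, truths, raw, p
    return stream, truths


# -- writers (round-trip with the readers in `windowing`) -----------------


def write_inertial_signals(
    windows: WindowSet, directory: str | Path, prefix: str = "chan"
) -> list[Path]:
    """Write the pre-windowed text layout: one whitespace-delimited file per
    channel (rows = windows) plus ``labels.txt``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in range(windows.windows.shape[2]):
        p = directory / f"{prefix}{c + 1}.txt"
        np.savetxt(p, windows.windows[:, :, c], fmt="%.6e")
        paths.append(p)
    np.savetxt(directory / "labels.txt", windows.labels, fmt="%d")
    return paths + [directory / "labels.txt"]


def write_signal_csv(record: SignalRecord, path: str | Path) -> Path:
    """Write the long-format CSV layout (time, channels..., label)."""
    path = Path(path)
    df = pd.DataFrame(
        record.samples, columns=[f"c{i + 1}" for i in range(record.n_channels)]
    )
    df.insert(0, "time", np.arange(record.n_samples) / record.rate)
    df["label"] = record.labels
    df.to_csv(path, index=False)
    return path
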