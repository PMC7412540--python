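"""Dempster-Shafer machinery over an activity frame of discernment.

Focal elements are subsets of the ``n`` activities, encoded as bitmasks
(bit ``i-1`` set means activity ``i`` is in the subset).  A basic probability
assignment (BPA) maps focal elements to nonnegative masses summing to 1 with
zero mass on the empty set.  Two regimes are supported:

* the *merged* regime, where each classifier's complement mass has been
  folded into the frame mass so every BPA lives on singletons plus the
  frame — combination stays (n+1)-dimensional;
* the *full powerset* regime (n <= 12), retained so the effect of the
  complement-merger strategy itself can be measured.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ActivityFrame",
    "BPA",
    "row_to_bpa",
    "merge_complement",
    "dempster_combine",
    "combine_many",
]

_MASS_EPS = 1e-12  # masses below this are clamped to keep long chains valid
_POWERSET_MAX_N = 12


@dataclasses.dataclass(frozen=True)
class ActivityFrame:
    """The universal set of mutually exclusive activity hypotheses."""

    names: tuple[str, ...]

    def __init__(self, names: Sequence[str] | int):
        if isinstance(names, int):
            names = tuple(f"a{i}" for i in range(1, names + 1))
        names = tuple(names)
        if len(names) < 2:
            raise ValueError("frame needs at least two activities")
        if len(set(names)) != len(names):
            raise ValueError("activity names must be unique")
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def theta(self) -> int:
        """Bitmask of the full frame."""
        return (1 << self.n) - 1

    def singleton(self, i: int) -> int:
        """Bitmask of activity ``i`` (1-based)."""
        if not 1 <= i <= self.n:
            raise ValueError(f"activity index {i} outside 1..{self.n}")
        return 1 << (i - 1)

    def complement(self, i: int) -> int:
        """Bitmask of all activities except ``i``."""
        return self.theta & ~self.singleton(i)


class BPA:
    """A mass function: nonnegative masses on nonempty subsets, summing to 1."""

    __slots__ = ("frame", "masses")

    def __init__(self, frame: ActivityFrame, masses: Mapping[int, float]):
        total = 0.0
        clean: dict[int, float] = {}
        for fe, m in masses.items():
            m = float(m)
            if m < -1e-9:
                raise ValueError(f"negative mass {m} on focal element {fe:b}")
            if fe == 0 and m > 1e-9:
                raise ValueError("empty set must carry zero mass")
            if fe == 0 or m <= _MASS_EPS:
                continue
            clean[fe] = clean.get(fe, 0.0) + m
            total += m
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"masses sum to {total}, expected 1")
        # renormalize away clamping residue
        self.masses = {fe: m / total for fe, m in clean.items()}
        self.frame = frame

    @classmethod
    def vacuous(cls, frame: ActivityFrame) -> "BPA":
        """Total ignorance: all mass on the frame."""
        return cls(frame, {frame.theta: 1.0})

    def mass(self, fe: int) -> float:
        return self.masses.get(fe, 0.0)

    def singleton_masses(self) -> np.ndarray:
        """Masses on the n singletons, index 0 <-> activity 1."""
        return np.array([self.mass(self.frame.singleton(i)) for i in range(1, self.frame.n + 1)])

    @property
    def is_vacuous(self) -> bool:
        return set(self.masses) <= {self.frame.theta}

    def close_to(self, other: "BPA", tol: float = 1e-9) -> bool:
        keys = set(self.masses) | set(other.masses)
        return all(abs(self.mass(k) - other.mass(k)) <= tol for k in keys)

    def __repr__(self) -> str:
        def label(fe):
            members = [self.frame.names[i] for i in range(self.frame.n) if fe >> i & 1]
            return "Θ" if fe == self.frame.theta else "{" + ",".join(members) + "}"

        inner = ", ".join(f"{label(fe)}: {m:.4f}" for fe, m in sorted(self.masses.items()))
        return f"BPA({inner})"

    # -- JSON round trip -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"frame": list(self.frame.names), "masses": {str(fe): m for fe, m in self.masses.items()}}
        )

    @classmethod
    def from_json(cls, text: str | Path) -> "BPA":
        if isinstance(text, Path):
            text = text.read_text()
        obj = json.loads(text)
        frame = ActivityFrame(obj["frame"])
        return cls(frame, {int(fe): m for fe, m in obj["masses"].items()})


def row_to_bpa(row: np.ndarray, i: int, frame: ActivityFrame) -> BPA:
    """Turn row ``i`` of a revised evidence matrix into a simple-support-style
    BPA: columns ``1..n`` are singleton masses (only column ``i`` can be
    nonzero after revision), column ``n+1`` is the row-specific complement
    set, and the final column is frame-level uncertainty."""
    row = np.asarray(row, dtype=np.float64)
    n = frame.n
    if row.shape != (n + 2,):
        raise ValueError(f"expected row of length n+2={n + 2}, got {row.shape}")
    if np.any(row < -1e-9):
        raise ValueError("revised evidence row has negative entries")
    masses: dict[int, float] = {}
    for j in range(1, n + 1):
        masses[frame.singleton(j)] = masses.get(frame.singleton(j), 0.0) + row[j - 1]
    comp = frame.complement(i)
    masses[comp] = masses.get(comp, 0.0) + row[n]
    masses[frame.theta] = masses.get(frame.theta, 0.0) + row[n + 1]
    return BPA(frame, masses)


def merge_complement(bpa: BPA, i: int) -> BPA:
    """Fold classifier ``i``'s complement mass into the frame mass.

    The complement of {a_i} cannot intersect {a_i}, so transferring its mass
    to the frame keeps the support for a_i intact while capping the focal
    set at singletons + frame — this is what prevents the 2^n - 1 focal
    explosion in the inter-classifier combination.
    """
    frame = bpa.frame
    allowed = {frame.singleton(i), frame.complement(i), frame.theta}
    extra = set(bpa.masses) - allowed
    if extra:
        raise ValueError(f"unexpected focal elements for classifier {i}: {extra}")
    merged = {
        frame.singleton(i): bpa.mass(frame.singleton(i)),
        frame.theta: bpa.mass(frame.theta) + bpa.mass(frame.complement(i)),
    }
    return BPA(frame, merged)


def dempster_combine(m1: BPA, m2: BPA) -> BPA:
    """Dempster's rule: conjunctive combination with conflict renormalization.

    ``m(B) = sum_{B1 ∩ B2 = B} m1(B1) m2(B2) / (1 - K)`` with
    ``K = sum_{B1 ∩ B2 = ∅} m1(B1) m2(B2)``.  Raises on total conflict
    (K = 1), where the evidence is non-combinable.
    """
    if m1.frame.names != m2.frame.names:
        raise ValueError("BPAs live on different frames")
    if m1.frame.n > _POWERSET_MAX_N and (len(m1.masses) > m1.frame.n + 1 or len(m2.masses) > m2.frame.n + 1):
        raise ValueError(f"full powerset combination refused for n > {_POWERSET_MAX_N}")
    out: dict[int, float] = {}
    conflict = 0.0
    for f1, v1 in m1.masses.items():
        for f2, v2 in m2.masses.items():
            inter = f1 & f2
            prod = v1 * v2
            if inter == 0:
                conflict += prod
            else:
                out[inter] = out.get(inter, 0.0) + prod
    if conflict >= 1.0 - 1e-12:
        raise ValueError("total conflict (K = 1): evidence is non-combinable")
    norm = 1.0 - conflict
    return BPA(m1.frame, {fe: v / norm for fe, v in out.items()})


def combine_many(bpas: Iterable[BPA]) -> BPA:
    """Left fold of Dempster's rule; associativity/commutativity make the
    result order-independent."""
    bpas = list(bpas)
    if not bpas:
        raise ValueError("need at least one BPA to combine")
    result = bpas[0]
    for b in bpas[1:]:
        result = dempster_combine(result, b)
    return result
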