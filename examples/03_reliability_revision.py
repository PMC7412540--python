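"""Reliability coefficients and evidence revision.

A classifier's softmax output is only as credible as the classifier.  From
held-out one-vs-rest confusion counts two coefficients are computed per
classifier — trust in its positive calls, TP/(TP+FP+FN), and in its
negative calls, TN/(TN+FN+FP) — and the evidence is discounted by them,
with the shaved-off mass booked as explicit uncertainty.
"""

import numpy as np

from evifuse import reliability_coefficients, revise_evidence
from evifuse.reliability import ConfusionCounts

# Held-out confusion counts for a six-activity bank: the confusable posture
# pair (classifiers 4 and 5) is clearly less precise than the rest.
counts = [
    ConfusionCounts(2290, 42, 12443, 65),
    ConfusionCounts(2279, 49, 12441, 71),
    ConfusionCounts(2076, 45, 12667, 52),
    ConfusionCounts(2153, 249, 11974, 464),
    ConfusionCounts(2338, 283, 11888, 331),
    ConfusionCounts(2720, 0, 12119, 1),
]
p = np.stack([reliability_coefficients(c, i, 6) for i, c in enumerate(counts, 1)])
for i in range(6):
    print(f"classifier {i + 1}: P_i = {p[i, i]:.4f}   P_n+1 = {p[i, 6]:.4f}")

# Revise one evidence matrix: every row keeps unit mass, with the
# discounted remainder moved to the new uncertainty column.
rng = np.random.default_rng(0)
e = rng.dirichlet(np.ones(7), size=6)
revised = revise_evidence(e, p)
print("\nrevised row of classifier 4 (last two columns: complement, uncertainty):")
print(np.round(revised[3], 3), " sum =", revised[3].sum().round(9))
# Classifier 4's weak precision (0.75) moves a quarter of its positive mass
# into uncertainty; classifier 6's near-perfect counts leave its row intact.
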