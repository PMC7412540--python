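"""Basic probability assignments and Dempster's combination rule.

Each revised evidence row becomes a BPA over the activity frame: mass on
the classifier's own activity, on its complement set, and on the whole
frame (uncertainty).  Dempster's rule fuses BPAs conjunctively,
renormalizing away conflicting (empty-intersection) mass; the complement
merger keeps the fusion (n+1)-dimensional instead of 2^n - 1.
"""

import numpy as np

import evifuse as ev

frame = ev.ActivityFrame(["walk", "stairs", "sit"])

row = np.array([0.6, 0.0, 0.0, 0.25, 0.15])  # support, ..., complement, uncertainty
bpa = ev.row_to_bpa(row, 1, frame)
print("classifier 1's BPA:          ", bpa)
merged = ev.merge_complement(bpa, 1)
print("after complement merger:     ", merged)

# Supportive evidence reinforces: combining two copies sharpens the support.
twice = ev.dempster_combine(merged, merged)
print("combined with itself:        ", twice)

# Conflicting evidence from another classifier is renormalized.
other = ev.BPA(frame, {frame.singleton(2): 0.5, frame.theta: 0.5})
fused = ev.combine_many([merged, other, ev.BPA.vacuous(frame)])
print("fused with a rival + vacuous:", fused)
# The vacuous BPA is the identity of the rule; the rival's support splits
# the mass, and whichever activity holds more combined mass wins the call.
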