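# Methods

## Model overview and assumptions

The recognizer treats each activity as an independent hypothesis.  Three
assumptions carry the design:

1. **Subinterval sufficiency.**  Any short window of a simple repetitive
   activity (a fraction of a gait cycle) carries enough information to
   recognize it, so windows can be much shorter than the activity period.
   This is what the evaluation index `I = Acc/(1 + Len/Con)` formalizes:
   accuracy saturates with length while latency grows linearly.
2. **Evidence reading of softmax outputs.**  A one-vs-rest classifier's
   softmax vector is evidence about its own activity and the merged
   complement, not a calibrated posterior.  Mass it places on categories it
   was never trained to discriminate is noise; reliability revision zeroes
   those positions and converts all discounted mass into frame-level
   uncertainty, so every row remains a valid mass function.
3. **Temporal persistence.**  Activities persist over many adjacent
   windows, so a classifier's evidence at nearby intervals is about the
   same hypothesis and may be conjunctively combined (intra-classifier
   fusion), with trainable weights controlling how far back and how hard.

## Parameters that matter

| parameter | default | units / range | rationale |
|---|---|---|---|
| window length | 20 samples (0.4 s at 50 Hz) | samples | index maximizer on the reference sweep; the 50%-overlap convention advances 10 samples per window |
| `Con` | 1000 | samples | must dwarf the longest candidate length (150) so the index penalizes latency gently and linearly |
| polynomial order | 13 | – | high enough to track the index's rise-and-fall over 150 lengths without ringing at the argmax |
| hidden sizes | 16/16/16/20/20/6 | neurons per layer (two equal layers) | per-classifier minima from the reference sweep: dynamic activities saturate at 16, the confusable postures need 20, lying needs almost nothing |
| bank optimizer | plain SGD, lr 0.002, batch 500, ≤200 epochs | – | the reference training regime |
| history sizes N_i | (2, 3, 3, 6, 6, 0) | past windows | per-classifier optima: combination window sizes 3/4/4/7/7/1; the confusable postures benefit from the longest time span (7 windows ≈ 1.6 s), lying from none |
| λ₂ | 0.0015 | – | penalty coefficient on the mapped weights |
| combiner optimizer | full-batch GD, lr 0.5, 150 epochs | – | the weight model has only ~20 sigmoid-mapped parameters; small learning rates leave it effectively untrained, 0.5 converges in ~100 epochs and the returned weights are the best-validation-epoch ones |
| θ filter | disabled | mass in [0,1] | drops classifier i from inter fusion when m(∁a_i)+m(Θ) > θ; off by default because its value is deployment-specific |

The weight reparameterization `W = σ(α)` keeps every discount in (0,1)
during training; the uncertainty position of each weight vector is pinned
at 1 because frame mass is the *absorber* of discounts and must not itself
be discounted (that would destroy row-mass conservation).

## What the synthetic generators emulate — and what they don't

`generate_signals` emulates the canonical 6-channel 50 Hz regime: three
dynamic activities as quasi-periodic sinusoids with distinct gait
frequencies (1.4–2.6 Hz), three postures as constant channel offsets, all
with additive Gaussian noise, and a deliberately near-identical pair
(sitting vs standing) reproducing the hardest confusion in real data.  It
does **not** emulate gait biomechanics, gravity-axis rotation, sensor
drift, or inter-subject variability; a bank that separates these signals
shows the pipeline is wired correctly, not that it would reach any
particular accuracy on real recordings.

`generate_evidence_stream` bypasses the signal/classifier stages and emits
one-vs-rest evidence directly, with controllable per-classifier accuracy,
AR(1)-correlated errors (correlation length 2 intervals), targeted
confusions, and optional label-independent noise classifiers.  Its defaults
mirror the quality pattern observed on real held-out data: dynamic
classifiers ~0.95, the confusable pair weaker *and asymmetric* (0.78/0.84)
*and overconfident* (support drawn from U(0.80, 0.98) against U(0.65, 0.95)
for the others), lying near-perfect (0.99).  Raw rows are pushed through
the package's actual tally → coefficients → revision machinery
("measured" mode), so the stream carries the same accuracy-reflecting
discounts a trained bank's output would; an "ideal" mode (all coefficients
1) exists for experiments that must isolate what the combiner's trainable
weights can discover on their own.  Truth sequences default to 100-interval
bouts (~20 s at the 0.4 s / 50% overlap granularity), the scale at which
scripted protocols switch activities.

Consequences for interpreting results: the directional ordering
maxout ≤ inter ≤ intra+inter demonstrated on these streams shows the
mechanisms work under realistic *structure* (confusability, miscalibration,
temporal persistence); the sizes of the gaps are properties of the
generator's noise regime, not predictions for real data.

## Numerical choices

- **Mass hygiene.**  Masses below 1e−12 are clamped to zero and the BPA
  renormalized, keeping long combination chains valid; the Dempster
  denominator 1−K is clamped at 1e−12 (K = 1 raises a total-conflict error
  in the reference path); singleton masses are clamped at 1e−12 inside the
  loss so a zero mass yields a large finite penalty rather than −∞.
- **Ties** in the final argmax go to the lowest activity index; a vacuous
  final evidence predicts activity 1 with a low-confidence flag.
- **Sequence start.**  Intervals with t < N_i fold only the available
  history.  Internally this is implemented by padding missing history with
  vacuous BPAs — the identity of Dempster's rule — which is exactly
  equivalent and keeps the training pass uniformly vectorized.
- **α initialization** at 0 (all weights 0.5) for symmetry.
- **Gradient path.**  Training differentiates through the entire
  discount → intra-fold → merger → inter-fold → loss computation by
  reverse-mode automatic differentiation (the in-package `autodiff` core,
  which also powers the LSTM bank); gradients are verified against central
  finite differences at 1e−5.

## Design choices at genuinely open points

- **Mixed-activity windows** get the majority per-sample label, ties to the
  earlier-occurring activity; `drop_mixed=True` excludes them instead.  The
  reference protocol used pre-labeled windows and never needed a rule.
- **Binary judgement for confusion tallies**: classifier i counts as
  positive when the argmax of its (n+1)-vector is position i.
  `fit_reliability` tallies whichever window set it is given; the pipeline
  and CLI pass held-out windows so the coefficients measure generalization,
  and passing the training split instead gives the train-data variant for
  ablations.
- **No output masking** on the (n+1)-way softmax even though only two label
  columns occur per classifier: revision is what removes off-target mass,
  matching the E ⊙ P mechanism exactly.
- **Weight granularity**: one α per (classifier, time offset), shared by
  the two active positions — the weight vector's first n+1 entries are
  equal by construction; a per-position variant is available via
  `CombinerConfig(per_position=True)`.
- **Merger-off (full powerset) regime** is supported for evaluation through
  the per-window reference path, with discounting applied before the focal
  set can expand; weight *training* runs in the merged regime only, which
  suffices because the two regimes agree to within a fraction of a percent
  on the evaluations this package runs (and the weighting mechanism is
  identical in both).  The powerset regime refuses frames larger than 12.
- **Maximizing the fitted index** uses dense-grid evaluation at 1-sample
  resolution rather than root-finding on the derivative: the decision is
  discrete, so the grid argmax is exact.
- **Regularization as printed**: the penalty is λ₂·ΣW² on the *mapped*
  weights, so its large-λ₂ limit drives weights toward 0 (the sigmoid floor),
  not toward the 0.5 midpoint.

## Problem sizes

The test suite and examples run at desk scale by the package's own choice:
evidence streams of 1.5–2.5 thousand intervals, banks of 2–6 subnetworks
with 5–8 hidden units trained for 15–30 epochs on a few hundred windows,
and combination-weight training of 150–200 full-batch epochs.  The
reference-scale experiment (six 16–20-unit subnetworks, ~750 k samples,
200 epochs) is supported by the same code paths but requires the external
recordings and several hours of CPU.

## Known limitations

- The LSTM bank trains with plain SGD; no momentum, scheduling, or class
  re-weighting.  One-vs-rest targets are 1:(n−1) imbalanced, so
  under-trained subnetworks collapse to always-negative before they learn —
  budget epochs accordingly.
- Dempster's rule is the only combination rule; highly conflicting evidence
  is renormalized, and total conflict is an error, not a fallback.
- The θ filter uses a hard, non-differentiable gate; gradients do not flow
  through the filtering decision.
- `count_weights` counts weight-matrix entries only (biases excluded), per
  its closed form `4((N_in+N_h1)N_h1 + (N_h1+N_h2)N_h2) + N_h2·N_out`.
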