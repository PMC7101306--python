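# Methods

This note documents the models, rules and numerical choices behind
`tdarx`, and what the shipped tests do and do not establish.

## Colour coding of clinical fields

Each of the 14 clinical fields and 5 joint channels has a total, ordered
rule mapping raw values to colour categories (green < yellow < orange <
red by severity). Cutoffs (units as stored):

| field | rule |
|---|---|
| RF (IU/mL) | green < 15, 15–30 yellow, ≥ 30 red |
| ACPA (U/mL) | green < 4.5, ≥ 4.5 red |
| ESR (mm/h) | green < 10, 10–20 yellow, ≥ 20 red |
| onset→visit (days) | yellow < 42, ≥ 42 red |
| CRP (mg/dL) | yellow < 0.3, ≥ 0.3 red |
| ANA (titre) | green < 40, 40–159 yellow, ≥ 160 red |
| MMP-3 (ng/mL) | yellow ≤ 120, > 120 red |
| WBC (/µL) | green < 4000, 4000–7999 yellow, ≥ 8000 red |
| gender | male yellow, female red |
| skin abnormality / trunk pain | negative green, positive yellow |
| body temperature (°C) | green < 37.5, 37.5–37.9 yellow, ≥ 38 red |
| patient/doctor VAS (0–100) | green < 10, 10–49 yellow, ≥ 50 red |
| joint symptom/tenderness/swelling | negative green, positive red |
| ultrasound GS / PD (0–3) | 0 green, 1 yellow, 2 orange, 3 red |

Boundary semantics: every interval is closed below and open above, so a
value equal to a cutoff takes the severer colour. MMP-3 is the one
exception (its cutoffs are conventionally printed as "< 120 / 121 ≤", a
one-unit gap that we close by keeping 120 itself yellow). ANA is stored
as a reciprocal titre; values between the standard dilutions discretize
through the same intervals. Onset-days and CRP have no green level;
ultrasound score 0, which the severity scale does not otherwise mention,
renders green like every other negative finding.

## Palette and decoding

Default RGB: green (0,176,80), yellow (255,255,0), orange (255,140,0),
red (255,0,0), background white, missing grey (128,128,128). All pairwise
Euclidean distances are ≥ 100 (the binding pair is yellow/orange at 115);
the decoder takes each block's centre-region mean colour and assigns the
nearest palette category, erroring if the distance exceeds half the
minimum palette distance. This makes `decode ∘ render = discretize` an
exact identity, which the suite verifies over 1000 random records.

## Layout

The canvas is 871 × 494 px. Each hand is a 5 × 3 grid of cruciform
blocks (18-px sub-squares: a above, b left, c centre, d right, e below;
DIP row on top, wrist bottom-right), the left panel an exact horizontal
mirror of the right; the 14 clinical squares (48 px) sit in two rows of
seven beneath. The published design fixes the canvas size, the block
inventory and the bilateral symmetry but shows the coordinates only
graphically; the shipped geometry is therefore this package's own
versioned stand-in (`layout-v1`, YAML-serializable), chosen so that no
rectangles overlap and renders are bit-exact.

## Synthetic cohorts

Continuous labs are sampled as `lo + LogNormal(ln m, σ)` truncated to the
printed range `[lo, hi]`, with `m` the printed median minus `lo` and
`σ = ln((hi−lo)/m)/3` (the range is read as spanning about ±3 log-sd).
When the printed median equals the minimum (nonRA ACPA, ANA), the
marginal becomes a 55% point mass at the minimum plus a small log-normal
tail. RA ACPA, whose learning-cohort median is not printed, is an
explicit seronegative mixture: 25% of RA draws are ACPA-negative
(a realistic seronegative-RA fraction), the rest log-normal with median
150 U/mL over the printed 0–3519 range. Body-temperature medians (only
ranges are published) and onset-day upper bounds (only quartiles are
published; we take 4× the upper quartile) are likewise package defaults.
Values are rounded to laboratory-plausible precision; ANA snaps to the
dilution grid 0, 40, 80, …, 2560.

Joint patterns are **invented defaults** (no per-joint prevalences were
published): RA involves wrist/MCP2–3 at 60–70% and PIPs at 35–50% with
bilateral symmetry 0.8 and GS/PD mass shifted upward; nonRA involves
DIPs at 35% with symmetry 0.3 and mostly low scores, an
osteoarthritis-like profile. Given involvement, symptom/tenderness/
swelling are Bernoulli draws and PD is capped at GS. With symmetry s,
the left joint is an exact copy of the right with probability s.

A `separation` knob interpolates every class parameter linearly toward
the pooled midpoint: 1.0 reproduces the class profiles, 0.0 makes the
classes identically distributed. Clinical and joint separation can be set
independently, which is how the ablation experiments construct cohorts
whose only signal is in the joint blocks.

What this does **not** emulate: cross-field covariance within a patient
(beyond the joint chain), longitudinal course, and real measurement
noise. Passing tests therefore validate the *pipeline* — encoding,
guards, protocol, metrics — under controlled class-conditional marginals,
not clinical performance on real patients.

## Augmentation

The source protocol expanded the learning data manually (one expert
edited each record, 1 → 6 for RA and 1 → 5 for nonRA, without affecting
the diagnosis). Those edits are unknowable, so the package substitutes a
stochastic policy with explicit guards: 10% relative jitter on continuous
fields, small flip/step probabilities on flags and ultrasound scores, at
most 4 fields changing colour category per clone, each by at most 1 level
on the field's own ordered category scale (a binary green/red channel
counts one step), and ACPA/RF categories frozen. "Cannot affect the
diagnosis" is thus operationalized as bounded category drift plus
protected serology — a software proxy, not a clinical re-adjudication.
Guards are enforced constructively (jitter that would break a bound is
clamped back into the original category's value interval) and re-verified
in tests by decoding rendered clones.

## Training protocol

Published settings kept as defaults: learning rate 0.001, at most 10
epochs, validation once per epoch on a fresh stratified 80/20 split per
trial, five independent trials, selection by best *test* accuracy (an
optimistic-bias caveat of the source protocol, replicated deliberately
and flagged in logs). Unpublished settings are package choices: SGD with
momentum 0.9, minibatch size 8 (at LR 0.001 × 10 epochs, larger batches
give too few updates to find single-block signals), nearest-neighbour
downscaling of the 871 × 494 raster to 64 × 64 network input (every
18-px sub-square still maps to at least one pixel, and all pixels remain
exact palette colours).

The default backbone (`small_cnn`) is a numpy implementation:
conv 5×5/stride 4 (12 filters) → ReLU → 2×2 max-pool → conv 3×3
(16 filters) → ReLU → 2×2 max-pool → dense 32 → dense 2, He
initialisation, softmax cross-entropy. `pretrained_transfer` freezes the
(seeded random) convolutional stack and trains only the fully connected
head — the final-layer-replacement transfer recipe with fixed random
features. Training is deterministic given the seed; trial t uses seed
`base_seed + 7919(t+1)` for both split and initialisation.

## Evaluation

RA is the positive class throughout (precision = TP/(TP+FP), recall =
TP/(TP+FN)). Report percentages are rounded half-up to integers, with
exact fractions retained; zero-denominator metrics are reported as
undefined, never as 0. Cohen's kappa uses the standard marginal-based
chance correction, with κ defined as 1 in the degenerate
all-agree/single-label case. The counterfactual probe re-renders a record
with one field replaced and reports the prediction pair; it never mutates
its input.

## Problem sizes

The shipped end-to-end checks run at desk scale by choice: 63 RA + 237
nonRA learning patients (augmented to 1563 images) with a 10 RA + 40
nonRA test cohort for the best-of-five run, and a balanced 60/60 + 20/20
joints-only-signal cohort (no augmentation, so chance is 0.5) for the
ablation comparison. Marginal-recovery checks use 10⁴ draws; round-trip
and augmentation-guard checks use 1000 records/clones.

## Known limitations

- The pixel geometry is a documented stand-in, not the original layout.
- Joint-pattern priors are invented; only the clinical marginals are
  anchored to published summaries.
- The numpy backbone is compact by design; it is not an 8-layer
  pretrained network, and no pretrained weights are downloaded.
- Best-of-five selection on the test set inflates the selected accuracy;
  use the per-trial accuracies when an unbiased estimate matters.
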