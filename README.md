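# tdarx

Colour-block image encoding of rheumatology clinical data, with CNN-based
classification of rheumatoid arthritis (RA) versus non-RA.

## The problem

There is no single diagnostic marker for RA. Rheumatologists integrate joint
symptoms, examination findings, serology (rheumatoid factor, ACPA),
inflammation markers (ESR, CRP), joint ultrasound and more — an assessment
that resists formula-based reproduction. One proposed route is to encode a
patient's whole first-visit work-up *semi-quantitatively* as a single small
colour image and let an image classifier learn the integrated pattern.

`tdarx` implements that pipeline end to end for researchers who want to
study and stress-test the approach:

- **Records** — a `PatientRecord` holds demographics, 7 laboratory values,
  symptom flags, two VAS scores and bilateral findings for 15 hand/wrist
  joint sites, each with 5 channels: symptom (a), tenderness (b),
  swelling (c), and OMERACT ultrasound grayscale (d) and power Doppler (e)
  scores, each 0–3. Lossless CSV/JSON serialization.
- **Encoder** — a deterministic rule table maps each field to an ordered
  colour category (green < yellow < orange < red; e.g. RF: green < 15,
  15–30 yellow, ≥ 30 red; GS/PD: 1 = yellow, 2 = orange, 3 = red), and a
  versioned layout renders the categories as one 871 × 494 RGB raster:
  30 plus-shaped ("cruciform") joint blocks in two mirrored hand panels and
  14 clinical squares. Images decode back to categories exactly.
- **Synthetic cohorts** — seeded generators whose class-conditional
  marginals match the published summary statistics of the learning
  (252 RA / 785 nonRA) and testing (10 RA / 40 nonRA) cohorts, with
  RA-typical symmetric wrist/MCP/PIP joint involvement versus a
  DIP-dominant osteoarthritis-like pattern, and a `separation` knob for
  power/robustness experiments.
- **Augmentation** — reproducible diagnosis-preserving expansion
  (each RA record 1 → 6, each nonRA record 1 → 5) under hard guards:
  labels never change, protected fields (ACPA, RF) keep their colour
  category, and at most a bounded number of fields may change category.
- **Training protocol** — five independent trials, each with a fresh
  stratified 80/20 train/validation split, at most 10 epochs at learning
  rate 0.001, validation once per epoch; the trial with the best test
  accuracy is selected. Backbone-agnostic; the default is a compact
  convolutional network in pure numpy.
- **Evaluation** — confusion matrix (RA positive), precision / recall /
  accuracy as integer percentages with exact fractions, Cohen's kappa
  κ = (p_o − p_e)/(1 − p_e), a three-way ablation (full image vs
  joints-only vs clinical-only), and a counterfactual probe that flips a
  single field (e.g. ACPA) and reports whether the prediction changes.

## Worked example

```python
import tdarx as T

# synthesize a learning cohort and an independent testing cohort
learning, _ = T.generate_cohort(63, 237, seed=11, profile="learning")
testing, _  = T.generate_cohort(10, 40, seed=12, profile="testing")

# expand 1 -> 6 (RA) / 1 -> 5 (nonRA) under the guarded default policy
expanded = T.expand_dataset(learning, T.AugmentationPolicy(seed=11))
len(expanded)        # 1563 = 63*6 + 237*5

# five independent trials, best-of-five selection
run = T.run_trials(expanded, testing, T.TrainingConfig(trials=5, base_seed=0))
run.accuracies       # [0.94, 0.98, 0.94, 0.98, 0.96]
run.selected_index   # 1

matrix = T.confusion([r.label for r in testing], run.selected.test_predictions)
print(matrix.as_table())
#                pred RA  pred nonRA
# true RA              9           1
# true nonRA           0          40
metrics = T.prf_accuracy(matrix)
metrics.precision_pct, metrics.recall_pct, metrics.accuracy_pct
# (100, 90, 98)
```

The five accuracies are the per-trial test accuracies; the selected trial
(index 1, 98%) classifies 49 of the 50 held-out synthetic patients
correctly, missing one RA case. Rendering a single record:

```python
img = T.render_tda(learning[0])     # 871 x 494 RGB raster
T.write_image(img, "patient.tiff")  # lossless; decodes back exactly
T.decode_tda(img)                   # {'rf': Category.RED, ...} for all 164 blocks
```

A CLI mirrors the library: `tda synth`, `tda encode`, `tda augment`,
`tda train`, `tda evaluate`, `tda probe` (see `tda --help`).

## Caveats

Selecting the best of five trials *by test accuracy* is part of the
protocol being replicated and is an optimistic-bias caveat of that
protocol; the harness flags it in its logs. Synthetic cohorts match
published marginals, not real patient covariance — see
`docs/methods.md` for what that does and does not validate.
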