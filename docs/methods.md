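# Methods

## Problem setting

`dftkit` implements discriminative fine-tuning (DFT) for small grayscale
image classifiers: instead of one global learning rate, every layer group
of the network receives its own learning rate and momentum, on the
rationale that earlier layers of a (pre)trained network encode primitive
features that need only small adjustments, while later layers and the
classifier head must move further.  The toolkit packages the full training
loop around that idea — rate-range selection, a triangular schedule,
chirality-preserving augmentation, minority oversampling, stratified
splitting, and multiclass sensitivity/specificity reporting — in a form
testable end to end on CPU with a built-in synthetic dataset generator.

## The DFT schedule

Two interpolations compose the schedule emitted by
`schedule.build_schedule`:

- **Across layers.** Layer group `l` of `l_max` gets the peak rate
  `alpha_min + (alpha_max − alpha_min) · l / (l_max − 1)` — a linear ramp
  from `alpha_min` (earliest group) to `alpha_max` (classifier head).  A
  single-group model takes `alpha_max`.
- **Across iterations.** One triangular cycle modulates the layer-wise
  spread over the run: a factor rises 0 → 1 over the first `kappa`
  fraction of iterations and falls 1 → 0 over the remainder.  The factor
  scales the spread *above* `alpha_min`, so no layer's rate ever drops
  below `alpha_min` — layers are never frozen mid-run.

Momentum interpolates `m_min → m_max` across layers during the rising
phase and mirrors (`m_max → m_min`) during the falling phase.  Since
cycling momentum *opposite* to the rate is common practice elsewhere, a
documented `invert_momentum` switch swaps the two phases.

The update applied per layer group is classical momentum SGD,

    v' = m · v − alpha · g        theta' = theta + v'

implemented as the pure function `dft_update`.  With `m = 0` it reduces
exactly to plain SGD, and with collapsed bounds the whole trainer
reproduces an independent SGD loop bit for bit — both reductions are
asserted in tests.

Design choices made where the design was genuinely open:

- `kappa` is a configuration knob (default 0.5), not a per-run random
  draw, so schedules are reproducible.
- One triangular cycle spans the whole run by default; per-epoch cycling
  is available via `TrainConfig(cycle="epoch")`.
- A "layer" is a parameter group in registration order (weights + bias of
  one convolution/linear block); the classifier head is always the last
  group.

## Learning-rate range test

`lr_finder.run_sweep` takes one plain-SGD step per candidate rate
(default: 60–150 geometrically spaced rates), recording raw and
exponentially smoothed loss (smoothing weight 0.98, debiased).  The sweep
aborts once the smoothed loss exceeds 4× its running minimum, and model
weights are restored afterward.

`select_bounds` automates the usual visual band choice: it scans
finite-difference slopes of smoothed loss against log-rate and takes the
right endpoint of the steepest *descending* segment as `alpha_max`, with
`alpha_min = alpha_max / 10`.  Two robustness measures matter in
practice, because single-batch losses are noisy and each rate receives
only one optimizer step:

- the slope is measured over a **window** of `n/20` consecutive points
  (curves under 40 points reduce to the consecutive-pair scan), so a lone
  one-step dip cannot outrank a sustained descent;
- `alpha_max` is additionally **capped at the rate of the curve's
  minimum**, so a selection can never land beyond the point where loss
  starts growing again.

A sweep whose loss never decreases raises `NoDescendingRegionError`
instructing a wider sweep.

## Augmentation

Four transforms, each mapping [0, 1] images to [0, 1] images of the same
shape:

| transform | formula | default sampling range |
|---|---|---|
| Gaussian blur | kernel ∝ exp(−(x²+y²)/(2v)), radius ⌈3√v⌉, sum 1 | v ∈ [0.25, 4] px² |
| gamma shift | I′ = clip(c·I^γ) | c ∈ [0.8, 1.2], γ ∈ [0.7, 1.5] |
| small rotation | bilinear resample about the center, zero fill | |φ| ∈ [2°, 15°], sign random (hard cap 25°) |
| white noise | I′ = clip(I + N(0, σ²)) | σ ∈ [0.005, 0.02] |

The ranges are chosen to be visually mild; they are deliberately not
dataset-calibrated.  The pipeline (`augment_dataset`) draws, per emitted
image, one source image with replacement, **one** transform, and one
parameter vector (chaining all transforms is available behind a flag);
labels are inherited.  Exact duplicates are rejected by an 8-bit content
hash, and horizontal mirroring is structurally absent from the registry —
mammographic anatomy is chiral, and the synthetic module provides a
marker/detector pair (`chirality_marker` / `detect_chirality`) that the
tests use to prove no transform flips an image.  Oversampling
(`oversample_minority`) duplicates minority-class indices uniformly with
replacement until every class matches the majority count, and is applied
to the training partition only, after splitting, to avoid leaking
duplicated images into validation or test.

## Metrics

With rows = actual and columns = predicted, one-vs-rest counts per class
are `TP_i = C_ii`, `FN_i = row_i − TP_i`, `FP_i = col_i − TP_i`,
`TN_i = total − TP_i − FN_i − FP_i`, giving multiclass sensitivity
`MSN_i = TP_i/(TP_i+FN_i)` and specificity `MSP_i = TN_i/(TN_i+FP_i)`.
Zero-denominator classes are reported as NaN with a defined-flag rather
than coerced to 0, and macro precision/recall average over defined
classes only — silent zeros would distort macro averages.  Tests verify
all of this against a brute-force per-sample counting oracle and against
scikit-learn.

## Trainer conventions

- Objective: `J = mean cross-entropy + λ‖θ‖²` (λ default 1e-4).
- Split: 80:15:5 stratified; overall sizes are rounded proportions with
  the remainder assigned to train, per-class quotas by largest-remainder.
- Batch size 64; epoch cap 50; best-validation-accuracy checkpoint with
  ties to the earlier epoch; images 400 px in the production default and
  64 px in the test configuration.
- Mixed precision is an emulated contract: the loss is multiplied by
  `loss_scale` before backpropagation, scaled gradients are stored in
  float16, then unscaled into float64 against full-precision master
  weights; a non-finite stored gradient skips the step (counted, never
  silently absorbed).  With float32 storage and scale 1 the step is
  bit-identical to the plain step.  There is no accelerator path; the
  contract exists so the numerical behavior of loss scaling is assertable
  on CPU.
- The model backend is a minimal numpy layer stack (strided 3×3
  convolutions via im2col, ReLU, average pooling, dense head) exposing
  the layer-group protocol (`param_groups`, `loss_and_grads`,
  `get_state`/`set_state`); any model honoring that protocol plugs into
  the trainer, the sweep and the schedule unchanged.

## Synthetic data generator

Each image is a smooth low-frequency random background plus a
class-specific pattern — a bright Gaussian blob whose position rotates
around the frame with the class index, and an oriented sinusoid whose
angle and frequency depend on the class — plus Gaussian pixel noise whose
standard deviation shrinks as `signal_strength` rises
(`0.02 + 0.25·(1 − signal_strength)`).  Label counts follow the requested
class proportions exactly via largest-remainder rounding.
`signal_strength = 0` removes the pattern entirely, so class-conditional
distributions coincide and any classifier sits at chance — the null case
the tests assert.

What the generator does *not* emulate: radiological texture, acquisition
physics, annotation noise, or inter-class similarity structure of real
BI-RADS categories.  Passing tests therefore demonstrate the correctness
of the training machinery and metrics, and the *relative* benefit of DFT
over a fixed small rate at desk scale — not clinical performance.

## Study conditions used by the verification runs

The convergence comparison (tests and `scripts/acceptance.py`) runs the
3-class, 600-image, 64 px, `signal_strength = 0.9` configuration: range
test (150 steps, 1e-4 → 10), then 10 epochs of DFT against a fixed-rate
baseline that applies `alpha_min` to every layer under the same momentum
policy, over several seeds; the compared statistic is the median epoch
index at which validation accuracy first reaches 95%.  These sizes keep a
full run in the low tens of seconds on one CPU core while still
exercising every layer of the stack; the package applies identically at
larger image sizes and epoch budgets.

## Known limitations

- The layer-wise ramp assumes feature "primitiveness" increases with
  registration order; unusual architectures may violate this.
- `select_bounds` assumes a single dominant descent region; multi-modal
  sweep curves select the steepest one, which may not be the widest.
- The numpy backend is CPU-bound and single-threaded beyond BLAS; it is
  a vehicle for the optimizer, not a general deep-learning framework.
- Mixed precision emulates storage rounding, not accelerator kernels.
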