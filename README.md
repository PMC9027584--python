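# dftkit

Discriminative fine-tuning for small grayscale image classifiers: every
layer group of a network gets its own learning rate and momentum, spread
by a triangular schedule, with the rate bounds chosen automatically by a
learning-rate range test.

The toolkit targets the common medical-imaging situation — a few hundred
labeled grayscale images (e.g., BI-RADS-graded mammograms), strong class
imbalance, no GPU budget — where fine-tuning converges faster and
overfits less when earlier layers move gently and later layers move
boldly.  Around the optimizer it provides the rest of the pipeline:
chirality-preserving augmentation (blur / gamma / small rotation / noise,
never mirroring), random minority oversampling, stratified 80:15:5
splitting, an emulated mixed-precision step contract, and multiclass
sensitivity/specificity metrics.  A synthetic dataset generator makes the
whole stack testable end to end on one CPU.

## The method

Layer group `l` of `l_max` (head last) receives the peak rate

    alpha_l = alpha_min + (alpha_max − alpha_min) · l / (l_max − 1)

and a triangular factor modulates the spread over the run — rising for
the first `kappa` fraction of iterations, falling for the remainder, never
dropping any layer below `alpha_min`.  Momentum interpolates
`m_min → m_max` across layers (mirrored in the falling phase).  Each group
is updated by momentum SGD:

    v ← m_l · v − alpha_l · ∇J(θ_l)        θ_l ← θ_l + v

with objective `J = mean cross-entropy + λ‖θ‖²`.  The bounds
`(alpha_min, alpha_max)` come from a range test: one SGD step per
geometrically increasing rate, with `alpha_max` placed at the steepest
sustained descent of smoothed loss versus log-rate and
`alpha_min = alpha_max / 10`.

## Worked example

```python
from dftkit import (SyntheticSpec, generate, split_dataset, SmallCNN,
                    SweepSpec, run_sweep, select_bounds,
                    TrainConfig, train_dft, evaluate)

ds = generate(SyntheticSpec(K=3, n=600, side=64, signal_strength=0.9, seed=1))
train, val, test = split_dataset(ds, (80, 15, 5), seed=1)

X, y = train.as_batch(), train.labels
batches = [(X[i:i+64], y[i:i+64]) for i in range(0, len(X), 64)]
model = SmallCNN(64, 3, seed=1)
curve = run_sweep(model, batches, SweepSpec(1e-4, 10.0, 150), seed=1)
bounds = select_bounds(curve)
print(f"alpha in [{bounds.alpha_min:.3g}, {bounds.alpha_max:.3g}]")

result = train_dft(model, train, val,
                   TrainConfig(epochs=10, batch_size=64, image_side=64, seed=1),
                   bounds)
print(f"best val accuracy {result.best_val_accuracy:.3f} "
      f"at epoch {result.best_epoch}")
cm, m = evaluate(model, test, K=3)
print(f"test accuracy {m.accuracy:.3f}")
```

Output:

```
alpha in [0.0154, 0.154]
best val accuracy 1.000 at epoch 3
test accuracy 1.000
```

The range test puts the productive rates near 0.02–0.2 for this model and
data; DFT then separates the three synthetic classes within two to three
epochs, and the held-out confusion matrix is diagonal (sensitivity and
specificity 1.0 for every class).  The same pipeline is scriptable from
the shell:

```
dftkit simulate --out-dir data --n 600 --k 3 --seed 1
dftkit augment  --in-dir data --out-dir data-aug --n-target 1200 --seed 1
dftkit lr-find  --in-dir data --out-dir lrf --seed 1
dftkit train    --in-dir data --out-dir run --bounds lrf/bounds.json --seed 1
dftkit evaluate --in-dir data --out-dir eval --checkpoint run/checkpoint.npz
```

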