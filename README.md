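# dilitracer

Severity-graded prediction of drug-induced liver injury (DILI) from
non-destructive brightfield imaging of 3D liver models. A sample is a time
series of z-stacks — T daily time points (Day 0–Day 3) × Z focal planes
(12–20) of grayscale frames — and the classifier assigns one of three
DILIrank-style concern levels: **vNo**, **vLess** or **vMost**-DILI-Concern.
The morphological signal is well characterized: unharmed organoids keep
growing into translucent hollow spheres, mildly affected ones arrest but
stay intact, and severely affected ones disintegrate into fragments from
about Day 2.

The package is aimed at computational biologists building image-based
toxicity screens: it contains the full model, a synthetic organoid-image
simulator so everything is testable without proprietary microscopy data, a
cross-validation training harness, ablation experiments, evaluation
statistics and attention-heatmap extraction. The neural network and its
optimizer run on a compact NumPy autodiff engine — no GPU or deep-learning
framework required.

## Model

The classifier factorizes a stack spatially and temporally:

1. **Image encoder** — a ViT: each frame is split into P×P patches
   (N = HW/P²), linearly embedded with positional embeddings, a learnable
   CLS token is prepended, and L pre-norm transformer blocks
   (zₗ′ = MSA(LN(zₗ₋₁)) + zₗ₋₁; zₗ = MLP(LN(zₗ′)) + zₗ′; y = LN(z_L))
   yield the image CLS vector H₀ per frame.
2. **Spatial encoder** — a two-block transformer over the Z image-CLS
   vectors of a day with its own CLS token; no z-positional encoding, so it
   is invariant to focal-plane order (Z varies between samples).
3. **Temporal encoder** — a bidirectional LSTM over the T daily spatial CLS
   vectors; the feature is the concatenated final forward/backward states.
4. **Head** — a small MLP producing three logits; softmax probabilities in
   the fixed class order (vNo = 0, vLess = 1, vMost = 2).

Training uses cross-entropy with AdamW (lr = 2e-4, batch 6, 100 epochs by
default) under stratified K-fold cross-validation (K = 5). A BEiT-style
masked-image-modeling mode (mask ratio 0.40, shared learnable mask
embedding, pixel regression of masked patches) provides a desk-scale
self-supervised warm start. See `docs/methods.md` for the full account.

## Worked example

Simulate a labeled dataset, cross-validate the classifier at desk scale,
and run the temporal ablation:

```python
import numpy as np
from dilitracer import cross_validate
from dilitracer.evaluation import ablation_report, run_ablation
from dilitracer.training import (
    DESK_MODEL_PARAMS, desk_train_config, make_benchmark_dataset,
)

data = make_benchmark_dataset(n_per_class=30, seed=1)     # 90 synthetic stacks
cfg = desk_train_config(seed=1)                           # 5-fold CV protocol
full = cross_validate(data, DESK_MODEL_PARAMS, cfg)
trunc = run_ablation(data, DESK_MODEL_PARAMS, cfg, mode="temporal_D0D1")

print("fold accuracies:", np.round([r.accuracy for r in full.fold_reports], 3))
print("mean CV accuracy:", round(full.mean_report.accuracy, 4))
print("per-class recall:", np.round(full.mean_report.recall, 3))
print("Day0-1 ablation accuracy:", round(trunc.mean_report.accuracy, 4))
print("drop (percentage points):",
      round(ablation_report(full.mean_report, trunc.mean_report)["accuracy_delta_pp"], 2))
```

Output (about eight minutes on one CPU core):

```
fold accuracies: [1.    0.944 1.    0.833 0.833]
mean CV accuracy: 0.9222
per-class recall: [0.9   1.    0.867]
Day0-1 ablation accuracy: 0.3444
drop (percentage points): 57.78
```

The full spatiotemporal model recovers the three phenotypes almost
perfectly, while the same protocol restricted to Day 0–Day 1 — before the
disintegration onset — collapses, confirming that the temporal dimension
carries the class signal by construction.

The estimator is sklearn-compatible
(`DILITracerClassifier().fit(X, y).predict_proba(X)`, `get_params`/
`set_params`), so it composes with `sklearn.model_selection` directly.
A `dilitracer` command-line interface wraps the same functionality:
`dilitracer simulate | split | train | evaluate | ablate | attend`.

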