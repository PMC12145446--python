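# Methods

## The classification model

`dilitracer` classifies a brightfield organoid sample — a grid of T daily
time points × Z focal planes of grayscale frames — into three
drug-induced-liver-injury (DILI) severity classes, in the fixed order
vNo-DILI-Concern = 0, vLess-DILI-Concern = 1, vMost-DILI-Concern = 2. The
network factorizes the stack the way video transformers factorize clips:

1. **Image encoder.** Each H×W×3 frame is cut into non-overlapping P×P
   patches (N = HW/P² of them), flattened and linearly embedded into D
   dimensions; learnable positional embeddings are added, a learnable CLS
   token is prepended, and L pre-norm transformer blocks
   (`x + MSA(LN(x))`, then `x + MLP(LN(x))`, k heads, head width D/k,
   GELU MLP of width 4D, sigmoid approximation x·σ(1.702x)) followed by a final layer norm produce the image
   CLS vector for that frame. Attention matrices are row-stochastic by
   construction and are retained for visualization.
2. **Spatial encoder.** The Z image-CLS vectors of one day, with their own
   learnable CLS token prepended, pass through a fixed two-block
   transformer and a final layer norm. No positional embedding is added
   along z: Z varies between samples (12–20 focal planes) and focal order
   carries no biology here, so the spatial summary is invariant to z-plane
   permutations — a tested contract.
3. **Temporal encoder.** A bidirectional LSTM runs over the T daily spatial
   CLS vectors; the feature vector is the concatenation of the final
   forward and final backward hidden states (length 2·hidden). Day order is
   information-bearing: reversing it changes the feature for generic
   weights, also a tested contract.
4. **Head.** A layer norm, a D-wide GELU layer and a linear map to three
   logits; probabilities are the softmax. Argmax ties resolve to the lowest
   class index.

A masked-image-modeling (MIM) mode supports desk-scale self-supervised
pretraining: ⌊ρN⌋ patch embeddings (ρ = 0.40 by default) are replaced by a
shared learnable mask embedding, and a single fully connected layer
regresses the normalized (preprocessed) pixel vectors of the masked patches;
the loss is the mean squared error over masked positions only. We regress
pixel vectors directly rather than per-patch-whitened pixels: whitening
turns near-uniform background patches into unit-variance noise targets that
cannot be predicted and would dominate the objective.

### Numerical core

The network, its gradients and the AdamW optimizer are implemented on a
compact NumPy reverse-mode automatic-differentiation engine
(`dilitracer._autograd`, `dilitracer._nn`), sized for desk-scale models.
Dense layers use fan-scaled (Glorot) truncated-normal initialization;
embedding-like parameters (CLS tokens, positional embeddings, mask token)
use truncated normal with σ = 0.02; LSTM weights are uniform ±1/√hidden.
Models run in float32 by default (float64 available via `STViT(dtype=)`;
the gradient unit tests verify the engine against numerical differentiation
in float64). Layer-norm epsilon is 1e-6 throughout. All computation is
deterministic given the seed: fits reproduce their final training loss to
well below 1e-6 on one machine.

### Why the head starts with an amplified layer norm

From random initialization the three encoder stages contract across-sample
differences: different samples map to nearly identical features, logits
differ by ~1e-3, and cross-entropy sits at ln 3 for tens of epochs before
feature learning starts ("uniform-softmax plateau"). Two measures shorten
this phase reliably and are defaults of the estimator: a feature layer norm
in front of the head whose gain is initialized at 4 (amplifying feature
differences into the logits without changing what the network can express),
and — in the desk-scale protocol — AdamW β₂ = 0.95, which shortens the
second-moment memory so that consistent gradient directions act sooner.
Neither changes the fitted model class; both only shape early optimization.

## Preprocessing and data handling

Frames are resized (bilinear, anti-aliased) to the model frame size
(224×224 reference geometry; the desk-scale protocol uses 64×64), grayscale
is replicated to three channels, intensities are scaled to [0, 1] (integer
inputs by their dtype maximum) and standardized with fixed constants
mean = 0.5, sd = 0.5, mapping to [−1, 1]. Fixed constants keep inference
independent of dataset composition.

The CSV index (one row per image: `sample_id,label,compound,platform,day,z,
path`) is validated on load: days must be contiguous from 0, the z-plane
count must be constant within a sample, and the label string must be one of
the three concern classes — the "Ambiguous DILI-concern" category is
rejected with an explicit error, never silently mapped, because its causal
evidence is insufficient for a class label by definition.

Cross-validation splits at the sample level, stratified by label (K = 5,
test fraction 1/K ± 1 sample). Whether real-world splits should also be
compound-disjoint is a judgment call on leakage; `split_kfold(...,
group_by="compound")` provides compound-disjoint folds for that analysis.

## Training protocol

Defaults follow the reference protocol: cross-entropy loss, AdamW
(lr = 2e-4, betas (0.9, 0.999), weight decay 0.01), batches of 6 samples,
100 epochs, no learning-rate schedule, no validation-based model selection
(the final-epoch model is evaluated). A batch's loss is the mean of
per-sample cross-entropies (tested against the per-sample oracle).

The estimator adds three optional training-efficiency devices, all off by
default and all orthogonal to the model contract:

- **MIM warm start** (`pretrain_epochs`): a few epochs of masked-patch
  regression before supervised training — the desk-scale counterpart of
  initializing the image encoder from a pretrained checkpoint.
- **z-plane sampling** (`train_z_planes`): each training step samples a
  fixed number of focal planes per sample, exactly as video transformers
  sample frames from a clip; valid because the spatial encoder is
  z-permutation invariant. Evaluation always uses every plane.
- **Dihedral augmentation** (`augment="dihedral"`): a random right-angle
  rotation plus optional flip per sample per step. Brightfield fields have
  no preferred orientation, so these are exact label-preserving symmetries.
  Without it the desk-scale fit memorizes 72 training samples (training
  accuracy 1.0) while held-out accuracy stalls near 0.78; with it held-out
  accuracy reaches ≥ 0.94.

## The synthetic organoid simulator

The simulator emulates the three morphological trajectories that distinguish
the severity classes in brightfield organoid imaging, so the full pipeline
is testable without the (request-only) experimental datasets:

- **vNo-DILI-Concern**: each organoid, rendered as a hollow sphere — a dark
  rim (Gaussian ring profile) with a slightly brightened translucent lumen
  on a bright background (0.82) — grows by 22 %/day in radius.
- **vLess-DILI-Concern**: growth arrest; geometry static across days.
- **vMost-DILI-Concern**: slight growth (4 %/day) until the disintegration
  onset day (default Day 2), after which the sphere is replaced by 3–6
  scattered dark blobs drawn once and kept for the remaining days.

Fields contain several organoids (placement rejects overlaps), each with its
own focal depth; a plane at offset Δz from an organoid's depth blurs that
organoid with a Gaussian of σ = defocus_sigma_per_plane·|Δz|, which makes
the z-axis informative. Z is drawn uniformly from 12–20 per sample; additive
Gaussian intensity noise (sd 0.02) is applied and frames are clipped to
[0, 1]. All randomness derives from the integer seed; identical calls are
bit-identical, and the on-disk dataset (16-bit TIFFs plus CSV index, no
timestamps) is byte-reproducible.

Pixel-valued defaults are expressed at a 224-px reference frame;
`SimConfig.scaled(size)` rescales the pixel geometry (radii, defocus) to
another frame size without touching the phenotype dynamics. The desk-scale
benchmark generates directly at 64 px.

What the simulator does **not** model: photorealistic texture, debris and
illumination gradients of real brightfield imaging, compound-specific
morphology, plate or batch effects, and HLO-vs-HepG2 differences beyond a
platform tag. Passing the end-to-end benchmark therefore demonstrates that
the architecture, training loop and evaluation machinery recover a
separable spatiotemporal phenotype signal — not that the model would reach
any particular accuracy on real organoid data.

A built-in check guarantees the learning task is solvable: two hand-crafted
features (final-day/day-0 foreground-area ratio; final-day/day-0
connected-component ratio, 8-connected with speckles below (0.018·size)²
pixels ignored) linearly separate 300 generated samples with ≥ 95 %
accuracy, and lose most of their power when restricted to Days 0–1, before
the disintegration onset — the construction behind the temporal ablation.

## Desk-scale benchmark

The end-to-end acceptance benchmark runs, per seed in {1, 2, 3}: 30
samples per class at 64 px, the tiny encoder (D = 64, L = 2, k = 4, P = 16,
LSTM hidden 64), 5-fold stratified CV, lr 2e-4, batch 3, 45 epochs, AdamW
betas (0.9, 0.95), six z-planes sampled per step, dihedral augmentation.
Problem sizes were chosen so the whole benchmark (three seeds plus the
temporal ablation) completes in tens of minutes on one CPU core. The
temporal ablation truncates every sample to Days 0–1 before training and
evaluation; the spatial ablation replaces each day's z-stack with one
focus-fused frame (per-pixel argmax of Laplacian variance in a 9×9 window
— a documented stand-in for instrument-side fusion) and bypasses the
spatial encoder. Measured with `scripts/acceptance.py`; the cross-validated
accuracy of the full model exceeds 0.90 while the Day 0–1 model loses tens
of percentage points, mirroring the direction of the reference ablations.

## Evaluation statistics

Multi-class rates are one-vs-rest per class: recall TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F1 the harmonic mean; overall accuracy is
the trace of the 3×3 confusion matrix over the total. Zero-denominator
rates return 0 and are flagged. ROC curves sweep each class's probability
(ties grouped so both axes step together); AUC uses the trapezoid rule and
is checked against exhaustive concordance-pair counting in the tests.
Cross-validation reports the arithmetic mean of fold metrics. Accuracy
differences between models are reported in percentage points.

## Attention maps

Per-image heatmaps aggregate the stored attention with head means and
attention rollout — the layer-wise product of row-normalized (A + I)/2 —
then take the CLS-to-patch row, reshape it to the patch grid, upsample
bilinearly to the frame and min–max normalize. Last-layer-only aggregation
is available. Overlays alpha-blend a matplotlib colormap over the frame and
write deterministic PNGs.

## Known limitations and degenerate cases

- Duplicating every z-slice is *not* an exact invariance: the spatial CLS
  token's self-attention mass is diluted by duplicated tokens, shifting
  probabilities by up to ~1/(Z+1); the tests assert that bound rather than
  exact equality.
- The spatial encoder accepts any Z ≥ 1, and the temporal encoder any
  T ≥ 1; empty sequences raise.
- AUC is undefined (raises) for a fold in which a class has no positives or
  no negatives; cross-validation flags such folds and averages the rest.
- `compute_metrics` on an all-zero confusion matrix raises; per-class
  zero-denominator cases are flagged, not raised.
- From-scratch training of larger configurations (224-px frames, deeper
  encoders) on tens of samples remains optimization-limited; the tiny
  desk-scale configuration is the supported from-scratch setting, and the
  MIM warm start is the intended route to larger ones.
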