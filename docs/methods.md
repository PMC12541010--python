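# Methods

## Problem and model

`acunet` segments brain tumors in multi-modal MRI. Each input is a stack of
four co-registered pulse-sequence channels (FLAIR, T1, T1CE, T2); the target
is a label map in the BraTS convention — 0 background, 1 necrotic /
non-enhancing core, 2 edema, 4 enhancing tumor — evaluated on the three
nested regions WT = {1, 2, 4}, TC = {1, 4} and ET = {4}. Volumes are
processed slice-wise: each 3-D scan is decomposed into axial 2-D slices that
are segmented independently, which keeps training and inference cheap enough
for CPU use.

The network is an encoder–decoder U-Net augmented with attention in three
places:

1. **Spatial attention.** Channel-wise max- and mean-pooling produce a
   2-channel map, a k×k convolution (default 7×7) and a sigmoid turn it into
   a per-position weight `A_s ∈ (0,1)^{H×W}` that rescales the feature map.
2. **Channel attention.** Global average pooling over space feeds a
   bottleneck MLP `C → C/r → C` (default r = 8) with ReLU then sigmoid,
   giving per-channel weights `A_c ∈ (0,1)^C`.
3. **Attention-gated skip connections** (full variant only). Before an
   encoder feature map `C_i` crosses its skip connection it is modulated by
   a coefficient computed from `C_i` together with the same-resolution
   decoder feature `U_i`. Two gate mechanisms are provided:
   `concat_sigmoid` (default), `α = σ(W_α^T [C_i, U_i] + b_α)` via a 1×1
   convolution on the channel concatenation, applied as `Ĉ_i = α · C_i`; and
   `qkv_softmax`, scaled dot-product attention over flattened spatial
   positions with `Q = W_q U_i`, `K = W_k C_i`,
   `α = softmax(QK^T / √d)` re-weighting the positions of `C_i`. Both are
   kept because they are distinct, reasonable gating mechanisms; the
   per-position sigmoid composes directly with `Ĉ_i = α_i · C_i` and is the
   default. The quadratic-cost QKV form is restricted to feature maps of at
   most 64×64 positions.

The spatial and channel branches run **in parallel** on the same input and
are fused by the elementwise mean of the two refined maps followed by a 1×1
convolution. The fusion operator is a design choice (the parallel-branch
idea fixes only that both act on the same features); the mean keeps the
refined scale and the 1×1 convolution lets training re-mix channels.

Each encoder level is two conv(3×3)+ReLU pairs with 'same' padding; widths
double per level from `base_width` (default 8) over `depth` levels (default
3); downsampling is 2×2 max-pooling, upsampling a learned 2×2 stride-2
transposed convolution; the head is a 1×1 convolution with per-pixel softmax
over the 4 classes. Region metrics are computed on WT/TC/ET masks derived
from the argmax labels, which reconciles multi-class training with
region-wise (effectively binary) evaluation.

### Ablation variants

`baseline` (no attention), `channel_only` / `spatial_only` (that branch
after every encoder and decoder block), `decoder_only` (dual attention on
decoder blocks only), `full` (dual attention on every block plus gated
skips). Baseline parameters are a strict subset of every variant's.

### Initialisation

Weights are He-initialised from the config seed. Sigmoid-producing attention
layers get a bias of +2 and the dual-fusion 1×1 convolution starts as the
identity, so every attention module is *nearly transparent at
initialisation* (α ≈ 0.88). With zero-centred biases each sigmoid gate
multiplies activations by ≈ 0.5, and stacking one or two gates per level
attenuates the forward signal geometrically with depth — in practice the
full variant then optimises markedly slower than the plain U-Net. Open-gate
initialisation is the standard remedy for gated architectures and does not
change what the modules can express.

## Losses and optimisation

Training minimises `L = λ_Dice·L_Dice + λ_CE·L_CE` with λ_Dice = λ_CE = 0.5
by default (the weighting is exposed; no canonical values exist). The
reference binary forms are `L_Dice = 1 − 2ΣPG / (ΣP + ΣG + ε)` and
`L_CE = −Σ[G log P + (1−G) log(1−P)]`; the training loop uses their
multi-class generalisations (soft Dice averaged over the 4 classes on
one-hot targets, categorical cross-entropy). Cross-entropy defaults to the
*mean* reduction so the learning rate is independent of image size; the sum
form is available to match the printed definition.

The optimiser is SGD, `θ ← θ − η·v` with momentum buffer
`v ← μ·v + ∇L` (μ = 0.9, η = 0.05, batch 8 by default — all exposed; no
authoritative values exist for this architecture). The entire network,
including convolutions, transposed convolutions, pooling, attention and the
softmax head, runs on a purpose-built reverse-mode autodiff engine over
float64 numpy arrays; its gradients are validated against central finite
differences both per-operation and end-to-end through a full-variant model.
Non-finite losses abort with a diagnostic rather than being skipped.
Checkpoint selection uses the best mean validation WT/TC/ET Dice over a
seeded 80/20 split of the fit data; early stopping uses a patience window.

Determinism: all randomness (weight init, splits, shuffling, augmentation,
phantom generation) flows through `numpy.random.Generator` objects derived
from explicit seeds, so a (data seed, model seed, train seed) triple fully
determines every reported number.

## Evaluation metrics

Overlap metrics come from exhaustive per-pixel confusion counts:
Dice = 2TP/(2TP+FP+FN), Jaccard = TP/(TP+FP+FN), precision, recall
(= sensitivity), specificity, F1 = 2PR/(P+R) (identical to Dice on binary
masks). Conventions when denominators vanish: both masks empty → overlap
scores 1; prediction empty only → 0.

Surface distances use boundary pixels — foreground pixels with at least one
background 4-neighbour, image border counted as background — and the exact
Euclidean distance transform scaled by voxel spacing (mm). HD95 is
`max(P95(pred→gt), P95(gt→pred))` with linearly-interpolated percentiles;
ASSD is the symmetric mean of all boundary-to-nearest-surface distances.
Both masks empty → 0; exactly one empty → NaN (undefined), excluded from
aggregate means and counted in the report. Per-region reports (rows WT, TC,
ET plus an arithmetic-mean "Average" row) serialise to CSV/JSON.

## Synthetic phantoms

The phantom generator makes the whole pipeline testable with no external
data. Each sample is one axial slice: per-channel base level 0.2, a smooth
low-frequency bias field (bicubic upsampling of 4×4 Gaussian noise,
amplitude 0.05), additive Gaussian noise (σ = 0.05), and — with probability
`tumor_probability` — three concentric random ellipses (random centre,
semi-axes 7–14 px on a 64×64 grid, rotation; TC and ET shrink the WT axes
by factors drawn from (0.55, 0.80) and (0.45, 0.70)) written as labels
2 / 1 / 4. Integer ellipse centres and a 1-px minimum semi-axis guarantee
all three regions are nonempty. Channel contrasts are additive offsets per
nested region chosen so channel 0 is bright across WT (FLAIR-like) and
channel 2 in ET (T1CE-like); a threshold on channel 0 approximately recovers
WT, which makes the task learnable by a small network in minutes — a
deliberate property so training-dependent tests are tractable.

What the phantoms do *not* emulate: MRI physics (Rician noise, partial
volume, motion), anatomy, inter-subject variability, non-elliptical or
multi-focal tumors, and class imbalance at realistic severity. Passing the
phantom study therefore demonstrates that the architecture, objective,
optimiser and evaluation stack are implemented correctly and that the model
can learn a contrast-coded nested-region task — not that it reaches
clinical-grade accuracy on real MRI.

## Study configuration and problem sizes

The bundled study uses 200 phantoms at 64×64, an 80/20 train/test split,
and a depth-3, width-8 full-variant model (~32 k parameters). The
learnability check trains 10 epochs; the baseline-vs-full ablation trains
both variants for 16 epochs (patience 12) under the identical seed, split,
preprocessing and loss, because the two variants converge at different
speeds (the baseline by ~6 epochs, the full variant learning the small ET
region around epoch 9–12) and an ablation is meaningful at convergence.
These sizes were chosen so the full study trains in minutes on one CPU
core while still exercising every component at realistic depth.

## Numerical choices and edge cases

- float64 throughout the network; ε = 1e-7 in Dice, 1e-12 clipping in CE.
- z-score normalisation is per-slice, per-channel over the whole slice
  (no brain mask); constant channels map to zeros under both modes.
- Masks are always resampled nearest-neighbour; images linearly. Scaling
  augmentation re-crops/pads centrally to the original shape.
- Max-pool gradient splits ties equally; softmax is computed with the
  max-subtraction trick; sigmoid uses the numerically stable two-branch
  form.
- Inputs whose spatial size is not divisible by 2^(depth−1) are zero-padded
  symmetrically and the output cropped back.
- Checkpoints are single-file `.npz` archives embedding the configuration
  JSON and its SHA-256 hash, validated on load.

## Known limitations

2-D slice-wise only (no 3-D context); no learning-rate schedules or
Adam-family optimisers; no bias-field correction, skull stripping or
registration; ROC/threshold-sweep plots are out of scope (class
probabilities are exported so external tools can draw them); the numpy
engine is CPU-bound and intended for small studies, not BraTS-scale
training.
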