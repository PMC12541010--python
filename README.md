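# acunet

An attention-based convolutional U-Net for brain-tumor segmentation on
multi-modal MRI, built for researchers who want a fully inspectable,
CPU-runnable implementation of the architecture, its training objective and
the BraTS-style evaluation protocol — including a synthetic phantom
generator so the entire pipeline runs and is tested without any external
dataset or GPU.

## The model

Input is a stack of four co-registered MRI channels (FLAIR, T1, T1CE, T2),
segmented slice-by-slice into the BraTS labels {0: background, 1: necrotic
core, 2: edema, 4: enhancing tumor} and evaluated on the nested regions
WT ⊇ TC ⊇ ET. On top of a standard U-Net encoder–decoder
(conv(3×3)+ReLU pairs, 2×2 max-pooling, transposed-convolution upsampling),
the network adds:

- **dual attention** — parallel spatial and channel branches on each
  feature map: `A_s = σ(conv_k([max_c x; mean_c x]))` per position and
  `A_c = σ(W₂ ReLU(W₁ GAP(x)))` per channel, fused by the elementwise mean
  of the refined maps plus a 1×1 convolution;
- **attention-gated skips** — encoder features are modulated before
  crossing each skip, `Ĉᵢ = αᵢ · Cᵢ` with
  `αᵢ = σ(W_α^T [Cᵢ, Uᵢ] + b_α)` (or, alternatively, scaled dot-product
  attention `softmax(QKᵀ/√d)` with decoder queries and encoder keys);
- a combined objective `L = λ_Dice·L_Dice + λ_CE·L_CE`, optimised by SGD
  with momentum.

Evaluation covers Dice, Jaccard, sensitivity, specificity, precision, F1,
HD95 (mm) and ASSD (mm) per region, k-fold cross-validation, and an
ablation harness over the variants *baseline*, *channel_only*,
*spatial_only*, *decoder_only* and *full*.

The network runs on a small reverse-mode autodiff engine over numpy arrays
(`acunet.nn`); its gradients are verified against finite differences in the
test suite. See `docs/methods.md` for the full model description,
parameter defaults and limitations.

## Worked example

```python
import numpy as np
from acunet import ACUNetSegmenter, PhantomSpec, generate_samples

# 200 synthetic 4-channel slices with nested elliptical tumors
samples = generate_samples(PhantomSpec(n_samples=200, shape=(64, 64), seed=7))
X = np.stack([s.image for s in samples])   # (200, 4, 64, 64)
y = np.stack([s.mask for s in samples])    # (200, 64, 64), labels {0,1,2,4}

est = ACUNetSegmenter(variant="full", depth=3, base_width=8,
                      epochs=10, seed=7)
est.fit(X[:160], y[:160])
print(est.region_dice(X[160:], y[160:]))
```

```
{'WT': 0.98526, 'TC': 0.82337, 'ET': 0.80610}
```

After ten epochs the model recovers the whole tumor almost perfectly
(WT Dice 0.985 on held-out slices) and the core regions well (TC 0.82,
ET 0.81, rising to ≈0.88 each by epoch 16). An untrained model scores
≈0.17 WT Dice on the same data. The estimator is sklearn-compatible (`get_params`/`set_params`,
`fit`/`predict`/`predict_proba`/`score`), so it composes with sklearn model
selection.

The same pipeline is available from the shell:

```bash
acunet make-phantoms --n 200 --shape 64 64 --seed 7 --out data/
acunet train    --data data/manifest.json --epochs 10 --out run/
acunet predict  --checkpoint run/checkpoint.npz --data data/manifest.json --out pred/
acunet evaluate --pred pred/ --data data/manifest.json --out eval/
acunet ablate   --data data/manifest.json --variants baseline,full --out abl/
acunet crossval --data data/manifest.json --k 5 --out cv/
```

`evaluate` prints the per-region metric table (Dice, Jaccard, sensitivity,
specificity, precision, F1, HD95 mm, ASSD mm, plus an Average row) and
writes it as CSV/JSON.

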