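"""scikit-learn style estimator wrapping the network and its training loop.

``ACUNetSegmenter`` follows the sklearn protocol: all hyperparameters are
constructor arguments handled by ``get_params``/``set_params``, ``fit`` learns
from arrays, fitted state lives in trailing-underscore attributes, and the
estimator composes with sklearn model selection.  Inputs are
``(n, channels, H, W)`` image stacks and ``(n, H, W)`` label maps over the
BraTS label set {0, 1, 2, 4}.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .metrics import confusion_counts, overlap_metrics
from .nn.autograd import Tensor
from .nn.network import ACUNet, ModelConfig, count_parameters
from .nn.objectives import combined_objective, one_hot
from .transforms import normalize_intensity, random_augment
from .volumes import ALLOWED_LABELS, REGION_ORDER, Sample2D, derive_regions

__all__ = ["ACUNetSegmenter"]

_LABEL_TO_CLASS = np.full(5, -1, dtype=np.int64)
for _i, _l in enumerate(ALLOWED_LABELS):
    _LABEL_TO_CLASS[_l] = _i
_CLASS_TO_LABEL = np.array(ALLOWED_LABELS, dtype=np.int16)


def _check_arrays(X, y=None):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 4:
        raise ValueError(f"X must be (n, channels, H, W), got shape {X.shape}")
    if y is None:
        return X, None
    y = np.asarray(y)
    if y.shape != (X.shape[0],) + X.shape[2:]:
        raise ValueError(f"y shape {y.shape} does not match X {X.shape}")
    if not np.isin(y, ALLOWED_LABELS).all():
        raise ValueError(f"labels must be in {ALLOWED_LABELS}")
    return X, y.astype(np.int64)


def sample_region_dice(pred_labels: np.ndarray, gt_labels: np.ndarray) -> dict:
    """Per-region Dice of one predicted label map against ground truth."""
    pr, gr = derive_regions(pred_labels), derive_regions(gt_labels)
    return {r: overlap_metrics(confusion_counts(pr[r], gr[r]))["dice"]
            for r in REGION_ORDER}


class ACUNetSegmenter(BaseEstimator):
    """Attention-based convolutional U-Net tumor segmenter.

    Parameters
    ----------
    variant : {'baseline', 'channel_only', 'spatial_only', 'decoder_only',
        'full'}
        Where attention is inserted (the ablation axis).
    gate_mode : {'concat_sigmoid', 'qkv_softmax'}
        Skip-connection gating mechanism (full variant only).
    depth, base_width : int
        Encoder levels and channel width at the finest level (doubling per
        level).
    epochs, batch_size, learning_rate, momentum : training loop controls;
        optimisation is SGD with momentum on the weighted Dice +
        cross-entropy objective (weights ``lambda_dice``/``lambda_ce``).
    val_fraction : float
        Held-out fraction of ``fit`` data used for checkpoint selection by
        mean WT/TC/ET Dice.
    patience : int
        Early-stopping patience in epochs without validation improvement.
    augment : bool
        Random flips/rotations/scaling on training samples.
    normalize : {'zscore', 'minmax', None}
        Per-slice, per-channel intensity standardisation applied inside
        ``fit``/``predict``.
    seed : int
        Drives weight init, the train/val split, shuffling and augmentation.
    """

    def __init__(self, variant: str = "full",
                 gate_mode: str = "concat_sigmoid",
                 depth: int = 3, base_width: int = 8,
                 in_channels: int = 4, n_classes: int = 4,
                 channel_reduction: int = 8, spatial_kernel: int = 7,
                 epochs: int = 10, batch_size: int = 8,
                 learning_rate: float = 0.05, momentum: float = 0.9,
                 lambda_dice: float = 0.5, lambda_ce: float = 0.5,
                 val_fraction: float = 0.2, patience: int = 5,
                 augment: bool = False, normalize: str | None = "zscore",
                 seed: int = 0):
        self.variant = variant
        self.gate_mode = gate_mode
        self.depth = depth
        self.base_width = base_width
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.channel_reduction = channel_reduction
        self.spatial_kernel = spatial_kernel
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.lambda_dice = lambda_dice
        self.lambda_ce = lambda_ce
        self.val_fraction = val_fraction
        self.patience = patience
        self.augment = augment
        self.normalize = normalize
        self.seed = seed

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(in_channels=self.in_channels,
                           n_classes=self.n_classes, depth=self.depth,
                           base_width=self.base_width, variant=self.variant,
                           gate_mode=self.gate_mode,
                           channel_reduction=self.channel_reduction,
                           spatial_kernel=self.spatial_kernel,
                           seed=self.seed)

    def _prep_images(self, X: np.ndarray) -> np.ndarray:
        if self.normalize is None:
            return X
        return np.stack([normalize_intensity(x, self.normalize) for x in X])

    def build_model(self) -> ACUNet:
        """Freshly initialised (untrained) network for this configuration."""
        return ACUNet(self._model_config())

    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Train on an (n, C, H, W) image stack and (n, H, W) label maps."""
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        X, y = _check_arrays(X, y)
        if X.shape[0] == 0:
            raise ValueError("empty dataset")
        X = self._prep_images(X)
        classes = _LABEL_TO_CLASS[y]

        seeds = np.random.SeedSequence(self.seed).spawn(3)
        split_rng = np.random.default_rng(seeds[0])
        loop_rng = np.random.default_rng(seeds[1])

        n = X.shape[0]
        n_val = int(round(n * self.val_fraction)) if n > 1 else 0
        perm = split_rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if tr_idx.size == 0:
            tr_idx, val_idx = perm, perm[:0]

        self.model_ = self.build_model()
        params = self.model_.parameters()
        buffers = [np.zeros_like(p.data) for p in params]

        history, best = [], (-np.inf, None)
        bad_epochs = 0
        for epoch in range(self.epochs):
            order = loop_rng.permutation(tr_idx)
            losses = []
            for start in range(0, order.size, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, cb = X[idx], classes[idx]
                if self.augment:
                    xb, cb = self._augment_batch(xb, cb, loop_rng)
                probs = self.model_.forward_tensor(Tensor(xb))
                loss = combined_objective(probs, one_hot(cb, self.n_classes),
                                          self.lambda_dice, self.lambda_ce)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}; "
                        "lower the learning rate")
                self.model_.zero_grad()
                loss.backward()
                for p, buf in zip(params, buffers):
                    buf *= self.momentum
                    buf += p.grad
                    p.data -= self.learning_rate * buf
                losses.append(float(loss.data))
            row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if val_idx.size:
                dices = self._region_dice(X[val_idx], y[val_idx])
                row.update({f"val_dice_{r.lower()}": dices[r]
                            for r in REGION_ORDER})
                score = float(np.mean([dices[r] for r in REGION_ORDER]))
            else:
                score = -row["train_loss"]
            history.append(row)
            if score > best[0] + 1e-12:
                best = (score, self.model_.state_dict())
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > self.patience:
                    break
        if best[1] is not None:
            self.model_.load_state_dict(best[1])
        self.history_ = pd.DataFrame(history)
        self.n_parameters_ = count_parameters(self.model_)
        self.best_val_score_ = best[0] if val_idx.size else None
        return self

    def _augment_batch(self, xb, cb, rng):
        xs, cs = [], []
        labels = _CLASS_TO_LABEL[cb]
        for img, msk in zip(xb, labels):
            s = random_augment(Sample2D(image=img, mask=msk), rng)
            xs.append(s.image)
            cs.append(_LABEL_TO_CLASS[np.asarray(s.mask, dtype=np.int64)])
        return np.stack(xs), np.stack(cs)

    def _region_dice(self, X_prepped, y_labels) -> dict:
        preds = self._predict_prepped(X_prepped)
        per = [sample_region_dice(p, g) for p, g in zip(preds, y_labels)]
        return {r: float(np.mean([d[r] for d in per])) for r in REGION_ORDER}

    # ------------------------------------------------------------------
    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def _predict_prepped(self, X, batch: int = 16) -> np.ndarray:
        out = []
        for start in range(0, X.shape[0], batch):
            probs = self.model_.forward(X[start:start + batch])
            out.append(_CLASS_TO_LABEL[probs.argmax(axis=1)])
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel class probabilities, shape (n, n_classes, H, W)."""
        self._require_fitted()
        X, _ = _check_arrays(X)
        X = self._prep_images(X)
        return np.concatenate([self.model_.forward(X[i:i + 16])
                               for i in range(0, X.shape[0], 16)])

    def predict(self, X) -> np.ndarray:
        """Argmax label maps in the BraTS label convention, shape (n, H, W)."""
        self._require_fitted()
        X, _ = _check_arrays(X)
        return self._predict_prepped(self._prep_images(X))

    def score(self, X, y) -> float:
        """Mean over samples of the mean WT/TC/ET Dice."""
        self._require_fitted()
        X, y = _check_arrays(X, y)
        preds = self._predict_prepped(self._prep_images(X))
        per = [np.mean(list(sample_region_dice(p, g).values()))
               for p, g in zip(preds, y)]
        return float(np.mean(per))

    def region_dice(self, X, y) -> dict:
        """Per-region Dice averaged over samples."""
        self._require_fitted()
        X, y = _check_arrays(X, y)
        return self._region_dice(self._prep_images(X), y)

    # ------------------------------------------------------------------
    def save(self, path) -> Path:
        """Serialise weights + configuration to a single .npz checkpoint."""
        self._require_fitted()
        path = Path(path)
        if not str(path).endswith(".npz"):
            path = Path(str(path) + ".npz")
        cfg_json = json.dumps({"model": self._model_config().to_dict(),
                               "params": self.get_params()}, sort_keys=True)
        blob = {f"w::{k}": v for k, v in self.model_.state_dict().items()}
        blob["__config__"] = np.frombuffer(cfg_json.encode(), dtype=np.uint8)
        blob["__hash__"] = np.frombuffer(
            hashlib.sha256(cfg_json.encode()).digest(), dtype=np.uint8)
        np.savez(path, **blob)
        return path

    @classmethod
    def load(cls, path) -> "ACUNetSegmenter":
        """Rebuild a fitted estimator from a checkpoint (validates config)."""
        with np.load(path) as data:
            cfg_json = bytes(data["__config__"]).decode()
            digest = hashlib.sha256(cfg_json.encode()).digest()
            if bytes(data["__hash__"]) != digest:
                raise ValueError("checkpoint config hash mismatch")
            cfg = json.loads(cfg_json)
            state = {k[3:]: data[k] for k in data.files if k.startswith("w::")}
        est = cls(**cfg["params"])
        est.model_ = est.build_model()
        est.model_.load_state_dict(state)
        est.n_parameters_ = count_parameters(est.model_)
        est.history_ = pd.DataFrame()
        return est
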