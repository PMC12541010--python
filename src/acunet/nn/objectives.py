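"""Differentiable training objectives (graph-node variants of the losses)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


def one_hot(classes: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, H, W) integer class map -> (N, n_classes, H, W) one-hot float grid."""
    return np.moveaxis(np.eye(n_classes)[classes], -1, 1)


def soft_dice_loss(probs: Tensor, target_onehot: np.ndarray,
                   eps: float = 1e-7) -> Tensor:
    """Mean over classes of 1 - 2*sum(P*G) / (sum(P) + sum(G) + eps)."""
    g = Tensor(target_onehot)
    inter = (probs * g).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + g.sum(axis=(0, 2, 3)) + eps
    dice = (inter * 2.0) / denom
    return (1.0 - dice).mean()


def ce_loss(probs: Tensor, target_onehot: np.ndarray,
            eps: float = 1e-12) -> Tensor:
    """Mean categorical cross-entropy over pixels."""
    g = Tensor(target_onehot)
    n_pix = target_onehot.shape[0] * target_onehot.shape[2] * target_onehot.shape[3]
    return -(g * probs.log(eps)).sum() * (1.0 / n_pix)


def combined_objective(probs: Tensor, target_onehot: np.ndarray,
                       lambda_dice: float, lambda_ce: float) -> Tensor:
    if lambda_dice < 0 or lambda_ce < 0 or lambda_dice + lambda_ce == 0:
        raise ValueError("loss weights must be nonnegative and not both zero")
    return (soft_dice_loss(probs, target_onehot) * lambda_dice
            + ce_loss(probs, target_onehot) * lambda_ce)
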