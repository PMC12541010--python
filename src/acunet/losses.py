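"""Segmentation losses: soft Dice, binary cross-entropy, weighted combination.

These are the plain-numpy reference forms operating on a predicted
probability grid ``P`` and a binary ground-truth grid ``G`` of equal shape.
The differentiable multi-class counterparts used inside the training loop
live in :mod:`acunet.nn.objectives`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossWeights", "dice_loss", "cross_entropy_loss", "combined_loss"]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the total loss L = lambda_dice * L_Dice + lambda_ce * L_CE."""

    lambda_dice: float = 0.5
    lambda_ce: float = 0.5

    def __post_init__(self):
        if self.lambda_dice < 0 or self.lambda_ce < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_dice == 0 and self.lambda_ce == 0:
            raise ValueError("loss weights must not both be zero")


def _check_pair(p: np.ndarray, g: np.ndarray) -> tuple:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def dice_loss(p, g, eps: float = 1e-7) -> float:
    """1 - 2*sum(P*G) / (sum(P) + sum(G) + eps), in [0, 1]."""
    p, g = _check_pair(p, g)
    return float(1.0 - 2.0 * (p * g).sum() / (p.sum() + g.sum() + eps))


def cross_entropy_loss(p, g, reduction: str = "mean",
                       eps: float = 1e-12) -> float:
    """Binary cross-entropy -sum[G log P + (1-G) log(1-P)].

    ``P`` is clipped into [eps, 1-eps] before the logarithms; ``reduction``
     'mean' divides the sum by the pixel count.
    """
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    p, g = _check_pair(p, g)
    p = np.clip(p, eps, 1.0 - eps)
    total = -float((g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).sum())
    return total / p.size if reduction == "mean" else total


def combined_loss(p, g, weights: LossWeights = LossWeights(),
                  reduction: str = "mean") -> float:
    """Weighted sum lambda_dice * L_Dice + lambda_ce * L_CE."""
    return (weights.lambda_dice * dice_loss(p, g)
            + weights.lambda_ce * cross_entropy_loss(p, g, reduction=reduction))
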