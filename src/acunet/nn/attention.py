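"""Attention modules: spatial, channel, their parallel fusion, and skip gates.

Spatial attention pools the feature map across channels (max and mean),
convolves the 2-channel result and squashes it through a sigmoid, producing a
per-position weight in (0, 1).  Channel attention global-average-pools over
space and passes the channel descriptor through a bottleneck MLP and sigmoid,
producing a per-channel weight.  The dual module runs both branches in
parallel on the same input and fuses the refined maps (elementwise mean
followed by a 1x1 convolution).

Skip-connection gates come in two flavours:

* ``concat_sigmoid`` — a per-position coefficient alpha = sigmoid(1x1 conv of
  the channel concatenation of encoder and decoder features); the encoder
  features are multiplied by alpha before crossing the skip.
* ``qkv_softmax`` — scaled dot-product attention over flattened spatial
  positions: the decoder features provide queries, the encoder features keys
  and values, alpha = softmax(Q K^T / sqrt(d)) row-wise.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, upsample_bilinear
from .layers import Conv2d, Linear, Module

# quadratic-cost guard: QKV attention over n positions builds an n x n matrix
MAX_QKV_POSITIONS = 64 * 64

# sigmoid bias at init: attention starts nearly transparent (alpha ~ 0.88)
# instead of halving every feature map, which would attenuate the forward
# signal multiplicatively with depth and stall early training
OPEN_GATE_BIAS = 2.0


class SpatialAttention(Module):
    def __init__(self, kernel: int, rng: np.random.Generator):
        self.conv = Conv2d(2, 1, kernel, rng)
        self.conv.bias.data[...] = OPEN_GATE_BIAS

    def attention_map(self, x: Tensor) -> Tensor:
        pooled = concat([x.max_along(1, keepdims=True),
                         x.mean(axis=1, keepdims=True)], axis=1)
        return self.conv(pooled).sigmoid()

    def __call__(self, x: Tensor):
        a = self.attention_map(x)
        return x * a, a


class ChannelAttention(Module):
    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.fc2.bias.data[...] = OPEN_GATE_BIAS
        self._channels = channels

    def attention_vector(self, x: Tensor) -> Tensor:
        gap = x.mean(axis=(2, 3), keepdims=False)          # (N, C)
        return self.fc2(self.fc1(gap).relu()).sigmoid()

    def __call__(self, x: Tensor):
        a = self.attention_vector(x)
        n = x.data.shape[0]
        return x * a.reshape(n, self._channels, 1, 1), a


class DualAttention(Module):
    """Parallel spatial + channel branches, mean-fused through a 1x1 conv."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int,
                 rng: np.random.Generator):
        self.spatial = SpatialAttention(spatial_kernel, rng)
        self.channel = ChannelAttention(channels, reduction, rng)
        # identity-initialised fusion: the dual module starts as a
        # near-transparent residual-style refinement
        self.fuse = Conv2d(channels, channels, 1, rng)
        self.fuse.weight.data[...] = np.eye(channels)[:, :, None, None]

    def __call__(self, x: Tensor) -> Tensor:
        rs, _ = self.spatial(x)
        rc, _ = self.channel(x)
        return self.fuse((rs + rc) * 0.5)


class AttentionGate(Module):
    """Gate encoder features with decoder context before the skip connection.

    The decoder feature map is bilinearly resized to the encoder's spatial
    shape when the resolutions differ.
    """

    def __init__(self, enc_channels: int, dec_channels: int, mode: str,
                 rng: np.random.Generator):
        if mode not in ("concat_sigmoid", "qkv_softmax"):
            raise ValueError(f"unknown gate mode {mode!r}")
        self.mode_ = mode
        if mode == "concat_sigmoid":
            self.alpha_conv = Conv2d(enc_channels + dec_channels, 1, 1, rng)
            self.alpha_conv.bias.data[...] = OPEN_GATE_BIAS
        else:
            d = enc_channels
            self.w_q = Conv2d(dec_channels, d, 1, rng, bias=False)
            self.w_k = Conv2d(enc_channels, d, 1, rng, bias=False)
            self._d = d

    def coefficients(self, enc: Tensor, dec: Tensor) -> Tensor:
        dec = upsample_bilinear(dec, enc.data.shape[2:])
        if self.mode_ == "concat_sigmoid":
            return self.alpha_conv(concat([enc, dec], axis=1)).sigmoid()
        n, c, h, w = enc.data.shape
        if h * w > MAX_QKV_POSITIONS:
            raise ValueError(
                f"qkv_softmax gate on {h}x{w} exceeds {MAX_QKV_POSITIONS} "
                "positions; use concat_sigmoid at fine resolutions")
        q = self.w_q(dec).reshape(n, self._d, h * w).transpose(0, 2, 1)
        k = self.w_k(enc).reshape(n, self._d, h * w).transpose(0, 2, 1)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self._d))
        return scores.softmax(axis=2)                       # (N, HW, HW) rows

    def __call__(self, enc: Tensor, dec: Tensor) -> Tensor:
        alpha = self.coefficients(enc, dec)
        if self.mode_ == "concat_sigmoid":
            return enc * alpha
        n, c, h, w = enc.data.shape
        v = enc.reshape(n, c, h * w).transpose(0, 2, 1)     # (N, HW, C)
        out = alpha @ v                                     # reweighted positions
        return out.transpose(0, 2, 1).reshape(n, c, h, w)
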