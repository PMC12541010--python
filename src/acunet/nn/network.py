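"""The attention-based convolutional U-Net and its ablation variants.

The network is a 2-D encoder-decoder segmenter.  Each encoder level applies a
double conv(3x3)+ReLU block and halves the resolution with 2x2 max-pooling;
channel width doubles per level.  The decoder mirrors the encoder with 2x2
stride-2 transposed convolutions, concatenating same-resolution encoder
features across skip connections before each decoder block.  A 1x1 convolution
and per-pixel softmax produce class probabilities.

Ablation variants control where attention is inserted:

===============  =============================================================
``baseline``     plain U-Net, no attention anywhere
``channel_only`` channel attention after every encoder and decoder block
``spatial_only`` spatial attention after every encoder and decoder block
``decoder_only`` dual (spatial + channel) attention on decoder blocks only
``full``         dual attention on every encoder and decoder block, plus
                 attention gates on every skip connection
===============  =============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, concat, maxpool2x2
from .attention import AttentionGate, ChannelAttention, DualAttention, SpatialAttention
from .layers import Conv2d, ConvBlock, ConvTranspose2x2, Module

VARIANTS = ("baseline", "channel_only", "spatial_only", "decoder_only", "full")
GATE_MODES = ("concat_sigmoid", "qkv_softmax")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``base_width`` is the channel count at the finest level; widths double
    with depth.  ``channel_reduction`` is the bottleneck ratio of the channel
    attention MLP.  ``seed`` drives weight initialisation.
    """

    in_channels: int = 4
    n_classes: int = 4
    depth: int = 3
    base_width: int = 8
    variant: str = "full"
    gate_mode: str = "concat_sigmoid"
    channel_reduction: int = 8
    spatial_kernel: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.gate_mode not in GATE_MODES:
            raise ValueError(f"gate_mode must be one of {GATE_MODES}")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelConfig keys: {sorted(unknown)}")
        return cls(**d)


def _make_attention(cfg: ModelConfig, channels: int, rng) -> Module | None:
    if cfg.variant == "channel_only":
        return ChannelAttention(channels, cfg.channel_reduction, rng)
    if cfg.variant == "spatial_only":
        return SpatialAttention(cfg.spatial_kernel, rng)
    if cfg.variant in ("decoder_only", "full"):
        return DualAttention(channels, cfg.channel_reduction,
                             cfg.spatial_kernel, rng)
    return None


def _apply_attention(mod, x: Tensor) -> Tensor:
    if mod is None:
        return x
    if isinstance(mod, DualAttention):
        return mod(x)
    out, _ = mod(x)
    return out


class ACUNet(Module):
    """Attention-gated U-Net segmenter over (N, C, H, W) inputs."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = [config.base_width * 2 ** i for i in range(config.depth)]
        enc_att = config.variant in ("channel_only", "spatial_only", "full")
        dec_att = config.variant in ("channel_only", "spatial_only",
                                     "decoder_only", "full")

        self.enc_blocks, self.enc_atts = [], []
        c_prev = config.in_channels
        for wdt in widths:
            self.enc_blocks.append(ConvBlock(c_prev, wdt, rng))
            self.enc_atts.append(_make_attention(config, wdt, rng)
                                 if enc_att else None)
            c_prev = wdt

        self.upconvs, self.gates, self.dec_blocks, self.dec_atts = [], [], [], []
        for lvl in range(config.depth - 2, -1, -1):
            self.upconvs.append(ConvTranspose2x2(widths[lvl + 1], widths[lvl], rng))
            self.gates.append(
                AttentionGate(widths[lvl], widths[lvl], config.gate_mode, rng)
                if config.variant == "full" else None)
            self.dec_blocks.append(ConvBlock(2 * widths[lvl], widths[lvl], rng))
            self.dec_atts.append(_make_attention(config, widths[lvl], rng)
                                 if dec_att else None)

        self.head = Conv2d(widths[0], config.n_classes, 1, rng)

    # -- inference ------------------------------------------------------------
    def forward_tensor(self, x: Tensor) -> Tensor:
        """Class probabilities as a graph node (used for training)."""
        if x.data.ndim != 4 or x.data.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W) input, "
                f"got {x.data.shape}")
        skips = []
        for i, block in enumerate(self.enc_blocks):
            x = _apply_attention(self.enc_atts[i], block(x))
            if i < self.config.depth - 1:
                skips.append(x)
                x = maxpool2x2(x)
        for i in range(self.config.depth - 1):
            enc = skips[-(i + 1)]
            x = self.upconvs[i](x)
            gated = self.gates[i](enc, x) if self.gates[i] is not None else enc
            x = self.dec_blocks[i](concat([gated, x], axis=1))
            x = _apply_attention(self.dec_atts[i], x)
        return self.head(x).softmax(axis=1)

    def forward(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities for a (N, C, H, W) array.

        Inputs whose spatial size is not divisible by 2**(depth-1) are
        zero-padded symmetrically and the output cropped back.
        """
        images = np.asarray(images, dtype=np.float64)
        squeeze = images.ndim == 3
        if squeeze:
            images = images[None]
        n, c, h, w = images.shape
        m = 2 ** (self.config.depth - 1)
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            images = np.pad(images, ((0, 0), (0, 0),
                                     (ph // 2, ph - ph // 2),
                                     (pw // 2, pw - pw // 2)))
        probs = self.forward_tensor(Tensor(images)).data
        if ph or pw:
            probs = probs[:, :, ph // 2:ph // 2 + h, pw // 2:pw // 2 + w]
        return probs[0] if squeeze else probs

    __call__ = forward


def build_model(config: ModelConfig) -> ACUNet:
    return ACUNet(config)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalars in ``model``."""
    return model.n_parameters()
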