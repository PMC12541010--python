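"""Parameterised building blocks: modules, convolutions, linear layers."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2x2


class Module:
    """Base class with recursive parameter discovery (insertion-ordered)."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]}")
        for k, v in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv2d(Module):
    """'Same' stride-1 convolution with He-initialised weights."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_he(rng, (c_out, c_in, kernel, kernel),
                                 c_in * kernel * kernel), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class ConvTranspose2x2(Module):
    """2x2, stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.weight = Tensor(_he(rng, (c_in, c_out, 2, 2), c_in * 4),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(_he(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvBlock(Module):
    """Two stacked conv(3x3) + ReLU pairs, the canonical U-Net level block."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()
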