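"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is a dynamic tape: every operation on :class:`Tensor` records its
parents and a closure that accumulates gradients into them.  Calling
``Tensor.backward()`` topologically sorts the tape and runs the closures in
reverse.  Only the operations the segmentation network needs are provided
(elementwise arithmetic with broadcasting, matmul, reductions, activations,
2-D convolution / transposed convolution / max-pooling, bilinear resizing,
softmax and concatenation).  Everything is float64 so finite-difference
gradient checks are meaningful.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "upsample_bilinear",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(self.data ** p, (self,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    __matmul__ = matmul

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_along(self, axis: int, keepdims: bool = True):
        """Max over one axis; ties share the gradient equally."""
        out = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out)
        cnt = mask.sum(axis=axis, keepdims=True)

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * (gg / cnt))

        return Tensor._make(out if keepdims else out.squeeze(axis), (self,), bw)

    # -- activations ----------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bw)

    def log(self, eps: float = 0.0):
        d = self.data + eps

        def bw(g):
            self._accum(g / d)

        return Tensor._make(np.log(d), (self,), bw)

    def softmax(self, axis: int = 1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        return Tensor._make(s, (self,), bw)


def concat(tensors, axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), bw)


# ---------------------------------------------------------------------------
# image ops (NCHW layout throughout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, ph: int, pw: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, H*W) patches of a stride-1 'same' correlation."""
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    n, c, hp, wp = xp.shape
    h, w = hp - kh + 1, wp - kw + 1
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, h, w), (s0, s1, s2, s3, s2, s3))
    return view.reshape(n, c * kh * kw, h * w)


def _corr2d_raw(x: np.ndarray, w: np.ndarray, ph: int, pw: int):
    """Stride-1 cross-correlation; returns (out, cols) with cols cached."""
    n, _, h, wid = x.shape
    co, ci, kh, kw = w.shape
    cols = _im2col(x, kh, kw, ph, pw)
    out = np.matmul(w.reshape(co, -1), cols).reshape(n, co, h + 2 * ph - kh + 1,
                                                     wid + 2 * pw - kw + 1)
    return out, cols


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """'Same' stride-1 2-D convolution (cross-correlation), odd kernels only."""
    co, ci, kh, kw = weight.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d supports odd kernel sizes only")
    ph, pw = kh // 2, kw // 2
    out, cols = _corr2d_raw(x.data, weight.data, ph, pw)
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1)
    n = x.data.shape[0]
    hw = out.shape[2] * out.shape[3]

    def bw(g):
        g2 = g.reshape(n, co, hw)
        if weight.requires_grad:
            weight._accum(np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
                          .reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            wflip = weight.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
            dx, _ = _corr2d_raw(g, np.ascontiguousarray(wflip), ph, pw)
            x._accum(dx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, bw)


def conv_transpose2x2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed conv with 2x2 kernel, stride 2 (exact 2x upsampling).

    weight has shape (c_in, c_out, 2, 2); output (N, c_out, 2H, 2W).
    """
    n, ci, h, w = x.data.shape
    _, co, _, _ = weight.data.shape
    out6 = np.einsum("ncij,cdab->ndiajb", x.data, weight.data)
    out = out6.reshape(n, co, 2 * h, 2 * w)
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1)

    def bw(g):
        g6 = g.reshape(n, co, h, 2, w, 2)
        if x.requires_grad:
            x._accum(np.einsum("ndiajb,cdab->ncij", g6, weight.data))
        if weight.requires_grad:
            weight._accum(np.einsum("ncij,ndiajb->cdab", x.data, g6))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, bw)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    x6 = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = x6.max(axis=(3, 5))
    mask = x6 == out[:, :, :, None, :, None]
    cnt = mask.sum(axis=(3, 5))

    def bw(g):
        share = (g / cnt)[:, :, :, None, :, None]
        x._accum((mask * share).reshape(n, c, h, w))

    return Tensor._make(out, (x,), bw)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D linear-interpolation matrix (half-pixel-centre convention)."""
    m = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = src - i0
    m[np.arange(n_out), i0] += 1.0 - f
    m[np.arange(n_out), i1] += f
    return m


def upsample_bilinear(x: Tensor, size: tuple) -> Tensor:
    ho, wo = size
    _, _, hi, wi = x.data.shape
    if (ho, wo) == (hi, wi):
        return x
    lh = _interp_matrix(ho, hi)
    lw = _interp_matrix(wo, wi)
    out = np.einsum("hH,ncHW,wW->nchw", lh, x.data, lw, optimize=True)

    def bw(g):
        x._accum(np.einsum("hH,nchw,wW->ncHW", lh, g, lw, optimize=True))

    return Tensor._make(out, (x,), bw)
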