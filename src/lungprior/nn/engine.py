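"""A compact CPU neural-network engine: reverse-mode autodiff over numpy.

Supports exactly the operations the segmentation harness needs — 3x3 and
1x1 convolutions, ReLU, sigmoid, 2x2 max-pooling, nearest-neighbor 2x
upsampling, channel concatenation, elementwise add/multiply (with
broadcasting) and binary cross-entropy on logits — together with an Adam
optimizer.  Everything is float32 and deterministic: identical seeds and
data orders reproduce identical weights bit for bit on CPU.
"""

from __future__ import annotations

from typing import Callable, List, Sequence

import numpy as np

__all__ = ["Tensor", "conv2d", "relu", "sigmoid", "maxpool2", "upsample2",
           "concat", "add", "mul", "bce_with_logits", "Adam"]

_DTYPE = np.float32


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded 2-D convolution: x (B,C,H,W), w (O,C,kh,kw), stride 1."""
    B, C, H, W = x.data.shape
    O, C2, kh, kw = w.data.shape
    assert C == C2, f"channel mismatch {C} vs {C2}"
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw \
        else x.data
    out = np.zeros((B, O, H, W), dtype=_DTYPE)
    for i in range(kh):
        for j in range(kw):
            out += np.einsum("oc,bchw->bohw", w.data[:, :, i, j],
                             xp[:, :, i:i + H, j:j + W], optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g: np.ndarray) -> None:
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    dw[:, :, i, j] = np.einsum(
                        "bohw,bchw->oc", g, xp[:, :, i:i + H, j:j + W],
                        optimize=True)
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + H, j:j + W] += np.einsum(
                        "oc,bohw->bchw", w.data[:, :, i, j], g,
                        optimize=True)
            dx = dxp[:, :, ph:ph + H, pw:pw + W] if ph or pw else dxp
            x._accumulate(dx)

    return Tensor(out, parents, backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return Tensor(s, (x,), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2 (H and W must be even)."""
    B, C, H, W = x.data.shape
    r = x.data.reshape(B, C, H // 2, 2, W // 2, 2)
    r = r.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
    idx = np.argmax(r, axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        dr = np.zeros_like(r)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dx = dr.reshape(B, C, H // 2, W // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        x._accumulate(dx)

    return Tensor(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        B, C, H2, W2 = g.shape
        dx = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        x._accumulate(dx)

    return Tensor(out, (x,), backward)


def concat(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]

    def backward(g: np.ndarray) -> None:
        start = 0
        for t, c in zip(tensors, sizes):
            if t.requires_grad:
                t._accumulate(g[:, start:start + c])
            start += c

    return Tensor(out, tuple(tensors), backward)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out, (a, b), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy evaluated on raw logits (numerically safe)."""
    z = logits.data
    y = np.asarray(targets, dtype=_DTYPE)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g: np.ndarray) -> None:
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(g * (s - y) / n)

    return Tensor(loss.mean(), (logits,), backward)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent (the standard defaults)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
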