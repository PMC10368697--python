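"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the 3D U-Net and its losses need. Volumes
are laid out channels-last, ``(N, D, H, W, C)``, so 3x3x3 convolutions
reduce to 27 shift-and-matmul steps that run through BLAS. Every primitive
with a hand-written backward pass is gradient-checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A numpy array plus gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, prev=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)
        self._backward = backward
        self._prev = tuple(prev)
        self.name = name

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'None'})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=np.float32)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise and reduction primitives


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, prev=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, prev=(a, b), backward=backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

    return Tensor(out_data, prev=(a, b), backward=backward)


def power(a: Tensor, p: float) -> Tensor:
    out_data = a.data**p

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * p * a.data ** (p - 1))

    return Tensor(out_data, prev=(a,), backward=backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * out_data)

    return Tensor(out_data, prev=(a,), backward=backward)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g / a.data)

    return Tensor(out_data, prev=(a,), backward=backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, prev=(a,), backward=backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a.accumulate(np.broadcast_to(g, a.shape))
        else:
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            a.accumulate(np.broadcast_to(gg, a.shape))

    return Tensor(out_data, prev=(a,), backward=backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), _wrap(1.0 / float(n)))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g.reshape(old))

    return Tensor(out_data, prev=(a,), backward=backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(p)

    return Tensor(out_data, prev=tuple(tensors), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return Tensor(out_data, prev=(a, b), backward=backward)


def prelu(a: Tensor, alpha: Tensor) -> Tensor:
    """Parametric rectifier with per-channel slope (channels-last)."""
    pos = a.data > 0
    out_data = np.where(pos, a.data, alpha.data * a.data)

    def backward(g):
        if a.requires_grad:
            a.accumulate(np.where(pos, g, alpha.data * g))
        if alpha.requires_grad:
            da = np.where(pos, 0.0, a.data) * g
            alpha.accumulate(_unbroadcast(da, alpha.shape))

    return Tensor(out_data, prev=(a, alpha), backward=backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a.accumulate(out_data * (g - dot))

    return Tensor(out_data, prev=(a,), backward=backward)


# ---------------------------------------------------------------------------
# spatial primitives (channels-last volumes)


def _conv_cl(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Raw same-padding convolution; x (N,D,H,W,C), w (k,k,k,C,Co)."""
    N, D, H, W, C = x.shape
    k = w.shape[0]
    Co = w.shape[-1]
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    acc = np.zeros((N * D * H * W, Co), np.float32)
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                xs = np.ascontiguousarray(
                    x[:, dz : dz + D, dy : dy + H, dx : dx + W, :]
                ).reshape(-1, C)
                acc += xs @ w[dz, dy, dx]
    return acc.reshape(N, D, H, W, Co)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding 3D convolution. x (N,D,H,W,Cin), w (k,k,k,Cin,Cout)."""
    out_data = _conv_cl(x.data, w.data)
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        k = w.shape[0]
        p = k // 2
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 1, 2, 3)))
        if w.requires_grad:
            N, D, H, W, C = x.shape
            xp = (
                np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x.data
            )
            gm = np.ascontiguousarray(g).reshape(-1, g.shape[-1])
            dw = np.empty_like(w.data)
            for dz in range(k):
                for dy in range(k):
                    for dx in range(k):
                        xs = np.ascontiguousarray(
                            xp[:, dz : dz + D, dy : dy + H, dx : dx + W, :]
                        ).reshape(-1, C)
                        dw[dz, dy, dx] = xs.T @ gm
            w.accumulate(dw)
        if x.requires_grad:
            wf = w.data[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
            x.accumulate(_conv_cl(np.ascontiguousarray(g), np.ascontiguousarray(wf)))

    prev = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, prev=prev, backward=backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2 (spatial dims must be even)."""
    N, D, H, W, C = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(D, H, W)}")
    win = (
        x.data.reshape(N, D // 2, 2, H // 2, 2, W // 2, 2, C)
        .transpose(0, 1, 3, 5, 7, 2, 4, 6)
        .reshape(N, D // 2, H // 2, W // 2, C, 8)
    )
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = (
            dwin.reshape(N, D // 2, H // 2, W // 2, C, 2, 2, 2)
            .transpose(0, 1, 5, 2, 6, 3, 7, 4)
            .reshape(N, D, H, W, C)
        )
        x.accumulate(dx)

    return Tensor(out_data, prev=(x,), backward=backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x upsampling of the three spatial dims."""
    out_data = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if not x.requires_grad:
            return
        N, D, H, W, C = x.shape
        dx = g.reshape(N, D, 2, H, 2, W, 2, C).sum(axis=(2, 4, 6))
        x.accumulate(dx)

    return Tensor(out_data, prev=(x,), backward=backward)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over all axes but the last (channel) axis.

    Running statistics are updated in place during training and used at
    evaluation time."""
    axes = tuple(range(x.data.ndim - 1))
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data
            if training:
                m = float(np.prod([x.shape[a] for a in axes]))
                dx = (
                    dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
                ) * inv
            else:
                dx = dxhat * inv
            x.accumulate(dx)

    return Tensor(out_data, prev=(x, gamma, beta), backward=backward)
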