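"""Network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter registry + train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and getattr(value, "requires_grad", False):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for m in self._modules.values():
            out.extend(m.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, p in self._params.items():
            out[name] = p.data.copy()
        for mname, m in self._modules.items():
            for k, v in m.state_dict().items():
                out[f"{mname}.{k}"] = v
        if isinstance(self, BatchNorm3d):
            out["running_mean"] = self.running_mean.copy()
            out["running_var"] = self.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self._params.items():
            p.data = state[name].copy()
        for mname, m in self._modules.items():
            sub = {
                k[len(mname) + 1 :]: v
                for k, v in state.items()
                if k.startswith(mname + ".")
            }
            m.load_state_dict(sub)
        if isinstance(self, BatchNorm3d):
            self.running_mean = state["running_mean"].copy()
            self.running_var = state["running_var"].copy()

    def checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.state_dict().values()))


class Conv3d(Module):
    """Same-padding 3D convolution, kernel size 1 or 3, channels-last."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel**3
        w = rng.normal(0, np.sqrt(2.0 / fan_in), (kernel, kernel, kernel, c_in, c_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return T.batchnorm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class PReLU(Module):
    """Parametric rectifier with a learnable per-channel slope."""

    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.alpha = Tensor(np.full(channels, init), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.prelu(x, self.alpha)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._zero = Tensor(np.zeros(1))

    def __call__(self, x: Tensor) -> Tensor:
        return T.prelu(x, self._zero)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.matmul(x, self.weight) + self.bias


def _activation(kind: str, channels: int) -> Module:
    if kind == "prelu":
        return PReLU(channels)
    if kind == "relu":
        return ReLU()
    raise ValueError(f"unknown activation {kind!r}")


class ConvBlock(Module):
    """Two 3x3x3 convolutions, each followed by normalization and a
    rectifier; optional residual shortcut (1x1x1 projection when channel
    counts differ)."""

    def __init__(self, c_in, c_out, rng, style="plain", activation="prelu"):
        super().__init__()
        self.style = style
        self.conv1 = Conv3d(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm3d(c_out)
        self.act1 = _activation(activation, c_out)
        self.conv2 = Conv3d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm3d(c_out)
        self.act2 = _activation(activation, c_out)
        if style == "residual" and c_in != c_out:
            self.shortcut = Conv3d(c_in, c_out, 1, rng)
        else:
            self.shortcut = None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.act1(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        if self.style == "residual":
            sc = self.shortcut(x) if self.shortcut is not None else x
            h = h + sc
        return self.act2(h)

    def conv_layer_count(self) -> int:
        n = 2
        if self.shortcut is not None:
            n += 1
        return n


class AuxHead(Module):
    """Patch-level classifier: global average pooling + linear + sigmoid."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.fc = Linear(channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(1, 2, 3))  # (N, C)
        return T.sigmoid(self.fc(pooled))


class DualAttention(Module):
    """Position + channel self-attention applied at the bridge.

    Position branch: queries/keys projected to C//8 channels, softmax
    affinity over the S = D*H*W positions re-weights values. Channel
    branch: softmax over the C x C channel affinity matrix. Each branch adds
    its output through a learnable scalar gate initialized at 0, so the
    block starts as an identity."""

    def __init__(self, channels: int, rng):
        super().__init__()
        c_red = max(channels // 8, 1)
        self.q = Conv3d(channels, c_red, 1, rng)
        self.k = Conv3d(channels, c_red, 1, rng)
        self.v = Conv3d(channels, channels, 1, rng)
        self.gamma_pos = Tensor(np.zeros(1), requires_grad=True)
        self.gamma_chan = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        N, D, H, W, C = x.shape
        S = D * H * W
        out = x
        # position attention (per batch element)
        q = self.q(x).reshape(N, S, -1)
        k = self.k(x).reshape(N, S, -1)
        v = self.v(x).reshape(N, S, C)
        for n in range(N):
            qn = _slice_batch(q, n)
            kn = _slice_batch(k, n)
            vn = _slice_batch(v, n)
            att = T.softmax(T.matmul(qn, _transpose2(kn)), axis=-1)  # (S, S)
            pos = T.matmul(att, vn).reshape(1, D, H, W, C)
            xn = _slice_batch(x.reshape(N, S, C), n).reshape(1, D, H, W, C)
            catt = T.softmax(T.matmul(_transpose2(_slice_batch(x.reshape(N, S, C), n)),
                                      _slice_batch(x.reshape(N, S, C), n)), axis=-1)
            chan = T.matmul(_slice_batch(x.reshape(N, S, C), n), catt).reshape(1, D, H, W, C)
            contrib = self.gamma_pos * pos + self.gamma_chan * chan
            out = out + _pad_batch(contrib, n, N)
        return out


def _slice_batch(x: Tensor, n: int) -> Tensor:
    data = x.data[n]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[n] = g
            x.accumulate(full)

    return Tensor(data, prev=(x,), backward=backward)


def _transpose2(x: Tensor) -> Tensor:
    data = x.data.T

    def backward(g):
        if x.requires_grad:
            x.accumulate(g.T)

    return Tensor(data, prev=(x,), backward=backward)


def _pad_batch(x: Tensor, n: int, N: int) -> Tensor:
    """Embed a single-sample tensor into an all-zero batch of size N."""
    data = np.zeros((N,) + x.shape[1:], np.float32)
    data[n] = x.data[0]

    def backward(g):
        if x.requires_grad:
            x.accumulate(g[n : n + 1])

    return Tensor(data, prev=(x,), backward=backward)
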