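"""Multi-task 3D U-Net: encoder/decoder with skip concatenations, optional
residual blocks and dual attention at the bridge, auxiliary patch-level
classifiers on decoder nodes, and a sigmoid voxel-probability output."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .layers import AuxHead, Conv3d, ConvBlock, DualAttention, Module
from .tensor import Tensor


@dataclass
class NetworkSpec:
    """Architecture knobs.

    ``depth`` is the number of 2x2x2 max-poolings; feature channels start at
    ``base_channels`` and double at every down-sampling step. The paper-scale
    model is depth=4, base 16; the desk-scale profile used for CPU-sized
    experiments is depth=3, base 8.
    """

    depth: int = 4
    base_channels: int = 16
    block_style: str = "plain"  # plain | residual
    attention: bool = False
    aux_tap_levels: tuple[str, ...] = ()  # subset of {"bridge", "mid", "top"}
    activation: str = "prelu"

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.block_style not in ("plain", "residual"):
            raise ValueError(f"unknown block style {self.block_style!r}")
        bad = set(self.aux_tap_levels) - {"bridge", "mid", "top"}
        if bad:
            raise ValueError(f"unknown aux tap levels {bad}")

    def channels_at(self, level: int) -> int:
        return self.base_channels * 2**level


class UNet3D(Module):
    def __init__(self, spec: NetworkSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        d = spec.depth
        # encoder
        for lvl in range(d):
            c_in = 1 if lvl == 0 else spec.channels_at(lvl - 1)
            setattr(
                self,
                f"enc{lvl}",
                ConvBlock(c_in, spec.channels_at(lvl), rng, spec.block_style, spec.activation),
            )
        self.bridge = ConvBlock(
            spec.channels_at(d - 1), spec.channels_at(d), rng, spec.block_style, spec.activation
        )
        self.attention = DualAttention(spec.channels_at(d), rng) if spec.attention else None
        # decoder: upsample + channel-halving 1x1x1 "up-conv", then a block
        for lvl in reversed(range(d)):
            setattr(self, f"up{lvl}", Conv3d(spec.channels_at(lvl + 1), spec.channels_at(lvl), 1, rng))
            setattr(
                self,
                f"dec{lvl}",
                ConvBlock(
                    2 * spec.channels_at(lvl),
                    spec.channels_at(lvl),
                    rng,
                    spec.block_style,
                    spec.activation,
                ),
            )
        self.final = Conv3d(spec.base_channels, 1, 1, rng)
        # prior-probability init: start near the background class so the
        # tiny-lesion dice/tversky gradients act from a sane baseline
        self.final.bias.data[:] = -3.0
        # auxiliary classification heads
        self._aux_specs: list[tuple[str, int]] = []
        mid = (d - 1) // 2
        taps = {"bridge": ("bridge", spec.channels_at(d)), "mid": (f"dec{mid}", spec.channels_at(mid)),
                "top": ("dec0", spec.channels_at(0))}
        for name in spec.aux_tap_levels:
            node, ch = taps[name]
            head = AuxHead(ch, rng)
            setattr(self, f"aux_{name}", head)
            self._aux_specs.append((node, name))

    # -- forward -----------------------------------------------------------
    def __call__(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Returns (voxel probabilities (N,D,H,W,1), per-head patch
        probabilities, each (N,1))."""
        d = self.spec.depth
        side = x.shape[1]
        if any(s % (2**d) for s in x.shape[1:4]):
            need = 2**d
            raise ValueError(
                f"input spatial shape {x.shape[1:4]} not divisible by 2^depth={need}; "
                f"pad each axis to a multiple of {need}"
            )
        node_out: dict[str, Tensor] = {}
        skips = []
        h = x
        for lvl in range(d):
            h = getattr(self, f"enc{lvl}")(h)
            skips.append(h)
            h = T.maxpool2(h)
        h = self.bridge(h)
        if self.attention is not None:
            h = self.attention(h)
        node_out["bridge"] = h
        for lvl in reversed(range(d)):
            h = getattr(self, f"up{lvl}")(T.upsample2(h))
            h = T.concat([skips[lvl], h], axis=-1)
            h = getattr(self, f"dec{lvl}")(h)
            node_out[f"dec{lvl}"] = h
        seg = T.sigmoid(self.final(h))
        aux = [getattr(self, f"aux_{name}")(node_out[node]) for node, name in self._aux_specs]
        return seg, aux

    # -- reporting ---------------------------------------------------------
    def conv_layer_count(self) -> int:
        """Number of convolutional layers (encoder + bridge blocks, decoder
        up-convs and blocks, final projection; attention/aux excluded)."""
        d = self.spec.depth
        n = sum(getattr(self, f"enc{l}").conv_layer_count() for l in range(d))
        n += self.bridge.conv_layer_count()
        n += sum(1 + getattr(self, f"dec{l}").conv_layer_count() for l in range(d))
        return n + 1


def build_model(spec: NetworkSpec, seed: int = 0) -> UNet3D:
    """Build a seeded multi-task 3D U-Net from an architecture spec."""
    return UNet3D(spec, seed)


def save_model(model: UNet3D, path, seed: int = 0) -> None:
    """Checkpoint: parameter arrays plus the architecture spec and seed."""
    import dataclasses
    import json

    state = model.state_dict()
    meta = {"spec": dataclasses.asdict(model.spec), "seed": seed}
    np.savez_compressed(path, __meta__=json.dumps(meta), **state)


def load_model(path) -> UNet3D:
    import json

    arrs = np.load(path, allow_pickle=False)
    meta = json.loads(str(arrs["__meta__"]))
    sd = meta["spec"]
    sd["aux_tap_levels"] = tuple(sd["aux_tap_levels"])
    spec = NetworkSpec(**sd)
    model = UNet3D(spec, seed=int(meta["seed"]))
    model.load_state_dict({k: arrs[k] for k in arrs.files if k != "__meta__"})
    return model.eval()
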