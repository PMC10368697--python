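"""Whole-volume prediction by tiling patches along the vessel skeleton.

Per-voxel probabilities of overlapping patches are averaged; voxels never
covered by any patch keep probability 0 (they are off the skeleton and by
construction were never candidates for an aneurysm call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..core import BinaryMask, ImageVolume
from ..patches import crop_padded
from ..skeleton import SkeletonVoxelSet
from .tensor import Tensor
from .unet import UNet3D


@dataclass
class Prediction:
    """Voxel probabilities over a grid plus optional patch-level classifier
    probabilities."""

    seg_probability: np.ndarray
    aux_probability: float | np.ndarray | None = None
    binarization_threshold: float = 0.5
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        p = np.asarray(self.seg_probability)
        if p.size and (p.min() < -1e-6 or p.max() > 1 + 1e-6):
            raise ValueError("probabilities must lie in [0, 1]")

    def mask(self) -> BinaryMask:
        return BinaryMask(
            (self.seg_probability > self.binarization_threshold).astype(np.uint8),
            self.spacing_mm,
        )


def tile_origins(
    skeleton: SkeletonVoxelSet,
    patch_size: tuple[int, int, int],
    stride: int,
    volume_shape: tuple[int, int, int],
) -> list[tuple[int, int, int]]:
    """Patch origins centered on a stride-decimated cover of the skeleton:
    one representative skeleton voxel per stride-sized grid cell (raster
    order, deterministic), origins clamped to keep patches inside the padded
    frame."""
    half = tuple(p // 2 for p in patch_size)
    seen = set()
    origins = []
    for c in skeleton.coordinates:
        cell = tuple(int(v) // stride for v in c)
        if cell in seen:
            continue
        seen.add(cell)
        origins.append(tuple(int(c[a]) - half[a] for a in range(3)))
    return origins


def predict_volume(
    model: UNet3D | None,
    img: ImageVolume,
    skeleton: SkeletonVoxelSet,
    patch_size: tuple[int, int, int] = (64, 64, 64),
    stride: int | None = None,
    batch_size: int = 8,
    threshold: float = 0.5,
    forward=None,
) -> Prediction:
    """Tile patches along the skeleton and average overlapping probability
    maps. ``forward`` may override the model call (maps a (N,D,H,W,1) array
    to probabilities of the same shape) — used for oracle tests."""
    stride = stride or max(patch_size[0] // 2, 1)
    prob = np.zeros(img.shape, np.float64)
    count = np.zeros(img.shape, np.float64)
    if len(skeleton) == 0:
        warnings.warn("empty skeleton: returning an all-zero prediction")
        return Prediction(prob, None, threshold, img.spacing_mm)
    origins = tile_origins(skeleton, patch_size, stride, img.shape)
    vol = np.asarray(img.voxels, np.float32)
    aux_all: list[float] = []
    if forward is None:
        def forward(batch_arr):
            seg, aux = model(Tensor(batch_arr))
            if aux:
                aux_all.extend(np.mean([a.data for a in aux], axis=0).ravel().tolist())
            return seg.data

    for start in range(0, len(origins), batch_size):
        chunk = origins[start : start + batch_size]
        batch_arr = np.stack(
            [crop_padded(vol, o, patch_size) for o in chunk]
        )[..., None]
        seg = np.asarray(forward(batch_arr))[..., 0]
        for o, pp in zip(chunk, seg):
            src, dst = [], []
            ok = True
            for a in range(3):
                s0 = max(o[a], 0)
                s1 = min(o[a] + patch_size[a], img.shape[a])
                if s0 >= s1:
                    ok = False
                    break
                dst.append(slice(s0, s1))
                src.append(slice(s0 - o[a], s1 - o[a]))
            if not ok:
                continue
            prob[tuple(dst)] += pp[tuple(src)]
            count[tuple(dst)] += 1.0
    covered = count > 0
    prob[covered] /= count[covered]
    aux = np.asarray(aux_all) if aux_all else None
    return Prediction(prob, aux, threshold, img.spacing_mm)


def classify_patches(
    model: UNet3D,
    samples,
    batch_size: int = 8,
    rule: str = "aux",
    min_voxels: int = 1,
    threshold: float = 0.5,
) -> list[Prediction]:
    """Per-patch predictions for the classification metric panel.

    ``rule='aux'``: patch is positive iff the mean auxiliary-head
    probability exceeds the threshold; ``rule='voxels'``: fallback rule —
    positive iff the binarized segmentation contains >= min_voxels voxels.
    """
    model.eval()
    out: list[Prediction] = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        arr = np.stack([s.image_patch for s in chunk])[..., None]
        seg, aux = model(Tensor(arr))
        segp = seg.data[..., 0]
        auxp = np.mean([a.data for a in aux], axis=0).ravel() if aux else None
        for i in range(len(chunk)):
            out.append(
                Prediction(
                    segp[i],
                    float(auxp[i]) if auxp is not None else None,
                    threshold,
                )
            )
    return out


def patch_decision(pred: Prediction, rule: str = "aux", min_voxels: int = 1) -> int:
    """Patch-level positive/negative decision from a Prediction."""
    if rule == "aux" and pred.aux_probability is not None:
        return int(np.asarray(pred.aux_probability).mean() > pred.binarization_threshold)
    return int((pred.seg_probability > pred.binarization_threshold).sum() >= min_voxels)
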