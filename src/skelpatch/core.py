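"""Core grid-aligned containers: scalar image volumes and binary masks.

Conventions used throughout the package:

* voxel arrays are indexed ``[x, y, z]`` with 0-based indices;
* ``spacing_mm`` / ``origin_mm`` are per-axis physical metadata in mm;
* NIfTI I/O goes through nibabel with a diagonal affine built from spacing
  and origin (no oblique orientations — phantoms and resampled volumes are
  always axis-aligned).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

Triple = tuple[float, float, float]


def _as_triple(v) -> Triple:
    t = tuple(float(x) for x in np.broadcast_to(v, (3,)))
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing and origin."""

    voxels: np.ndarray
    spacing_mm: Triple = (1.0, 1.0, 1.0)
    origin_mm: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return replace(self, voxels=voxels)

    def physical_extent_mm(self) -> Triple:
        return _as_triple([n * s for n, s in zip(self.shape, self.spacing_mm)])

    # -- NIfTI I/O ---------------------------------------------------------
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32), self.affine())
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(np.asarray(img.dataobj, dtype=np.float32), spacing, origin)


@dataclass
class BinaryMask:
    """A {0,1} grid aligned to an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing_mm: Triple = (1.0, 1.0, 1.0)
    origin_mm: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {v.shape}")
        vals = np.unique(v)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values outside {{0,1}}: {vals[:10]}")
        self.voxels = v.astype(np.uint8)
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def astype_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    def count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return self.count() == 0

    def with_voxels(self, voxels: np.ndarray) -> "BinaryMask":
        return replace(self, voxels=voxels)

    def same_grid(self, other: "ImageVolume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.voxels.astype(np.uint8), self.affine())
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "BinaryMask":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        data = np.asarray(img.dataobj)
        return cls((data > 0.5).astype(np.uint8), spacing, origin)


def require_same_grid(a, b, what: str = "operands") -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what} live on different grids: {a.shape} vs {b.shape}")
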