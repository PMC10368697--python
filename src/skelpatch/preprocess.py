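"""Volume normalization: percentile clipping + z-score, bias-field
correction, isotropic resampling, and a pluggable brain-mask step.

Order of the full pipeline: bias correction (on raw intensities, where the
multiplicative-field model holds) -> isotropic resampling -> percentile
clipping + z-score standardization last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .core import BinaryMask, ImageVolume, require_same_grid


@dataclass
class PreprocessConfig:
    clip_percentiles: tuple[float, float] = (0.5, 99.5)
    target_spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    bias_correction: bool = True
    bias_method: str = "polyfit"  # or "n4"
    brain_mask_strategy: str = "none"  # none | threshold | file:<path>

    def __post_init__(self):
        lo, hi = self.clip_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"bad clip percentiles ({lo}, {hi})")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")


def clip_and_standardize(img: ImageVolume, cfg: PreprocessConfig | None = None) -> ImageVolume:
    """Clip to the [p_low, p_high] percentile interval, then z-score.

    Percentiles use linear interpolation between order statistics
    (numpy's default rule); the mean/std are those of the clipped volume, so
    the output has mean 0 and unit standard deviation by construction.
    """
    cfg = cfg or PreprocessConfig()
    v = np.asarray(img.voxels, np.float64)
    if np.unique(v).size < 2:
        raise ValueError("constant image: z-score is undefined")
    lo, hi = np.percentile(v, cfg.clip_percentiles)
    clipped = np.clip(v, lo, hi)
    std = clipped.std()
    if std == 0:
        raise ValueError("image is constant after clipping: z-score undefined")
    out = (clipped - clipped.mean()) / std
    return img.with_voxels(out.astype(np.float32))


def _poly_design(shape, order: int, idx: tuple[np.ndarray, ...]) -> np.ndarray:
    coords = [2.0 * idx[a] / max(shape[a] - 1, 1) - 1.0 for a in range(3)]
    cols = [np.ones_like(coords[0])]
    for px in range(order + 1):
        for py in range(order + 1 - px):
            for pz in range(order + 1 - px - py):
                if px == py == pz == 0:
                    continue
                cols.append(coords[0] ** px * coords[1] ** py * coords[2] ** pz)
    return np.stack(cols, axis=1)


def estimate_bias_field(
    img: ImageVolume, mask: BinaryMask, order: int = 2
) -> np.ndarray:
    """Least-squares fit of a smooth polynomial field to log-intensities
    inside the mask; returned field has mean 1 inside the mask.

    The fit uses only the bulk of the masked intensity distribution (inside
    the [2, 90] percentile band) so sparse bright structures such as vessels
    do not masquerade as inhomogeneity."""
    require_same_grid(img, mask, "image/mask")
    v = np.asarray(img.voxels, np.float64)
    m = mask.astype_bool()
    lo, hi = np.percentile(v[m], (2.0, 90.0))
    fit_m = m & (v >= lo) & (v <= hi)
    if fit_m.sum() < 100:
        fit_m = m
    vals = v[fit_m]
    shift = 0.0
    vmin = vals.min()
    if vmin <= 0:
        shift = 1.0 - vmin
    logv = np.log(vals + shift)
    idx = np.nonzero(fit_m)
    A = _poly_design(img.shape, order, idx)
    coef, *_ = np.linalg.lstsq(A, logv, rcond=None)
    full_idx = tuple(g.ravel() for g in np.indices(img.shape))
    field = np.exp(_poly_design(img.shape, order, full_idx) @ coef).reshape(img.shape)
    field /= field[m].mean()
    return field.astype(np.float64)


def _cv(values: np.ndarray) -> float:
    mu = values.mean()
    return float(values.std() / abs(mu)) if mu != 0 else np.inf


def correct_bias(
    img: ImageVolume,
    mask: BinaryMask,
    method: str = "polyfit",
    order: int = 2,
) -> ImageVolume:
    """Remove smooth multiplicative intensity inhomogeneity.

    ``polyfit`` fits a log-domain polynomial field inside the mask (the
    default: fast, deterministic); ``n4`` delegates to SimpleITK's N4
    implementation. Contract: the within-mask coefficient of variation never
    increases (if an estimated field would increase it, the input is
    returned unchanged).
    """
    if mask.count() < 100:
        warnings.warn("degenerate mask (< 100 voxels): bias correction skipped")
        return img
    m = mask.astype_bool()
    if method == "polyfit":
        field = estimate_bias_field(img, mask, order=order)
        corrected = np.asarray(img.voxels, np.float64) / field
    elif method == "n4":
        import SimpleITK as sitk  # optional backend

        im = sitk.GetImageFromArray(np.asarray(img.voxels, np.float32).transpose(2, 1, 0))
        im.SetSpacing(tuple(img.spacing_mm))
        mk = sitk.GetImageFromArray(mask.voxels.transpose(2, 1, 0))
        mk.SetSpacing(tuple(img.spacing_mm))
        corrector = sitk.N4BiasFieldCorrectionImageFilter()
        res = corrector.Execute(im, sitk.Cast(mk, sitk.sitkUInt8))
        corrected = sitk.GetArrayFromImage(res).transpose(2, 1, 0).astype(np.float64)
    else:
        raise ValueError(f"unknown bias correction method {method!r}")
    if _cv(corrected[m]) > _cv(np.asarray(img.voxels, np.float64)[m]):
        warnings.warn("bias correction would increase within-mask CV; passthrough")
        return img
    return img.with_voxels(corrected.astype(np.float32))


def resample_isotropic(
    img: ImageVolume, target_spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
) -> ImageVolume:
    """Resample to the target spacing with trilinear interpolation,
    preserving physical extent to within one voxel per axis."""
    if any(s <= 0 for s in target_spacing_mm):
        raise ValueError("target spacing must be positive")
    if np.allclose(img.spacing_mm, target_spacing_mm):
        return img
    new_shape = [
        max(int(round(n * s / t)), 1)
        for n, s, t in zip(img.shape, img.spacing_mm, target_spacing_mm)
    ]
    zoom = [ns / n for ns, n in zip(new_shape, img.shape)]
    out = ndi.zoom(np.asarray(img.voxels, np.float32), zoom, order=1, mode="nearest")
    return ImageVolume(out, tuple(target_spacing_mm), img.origin_mm)


def resample_mask(
    mask: BinaryMask, target_spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
) -> BinaryMask:
    """Nearest-neighbor resampling; output stays strictly binary."""
    if any(s <= 0 for s in target_spacing_mm):
        raise ValueError("target spacing must be positive")
    if np.allclose(mask.spacing_mm, target_spacing_mm):
        return mask
    new_shape = [
        max(int(round(n * s / t)), 1)
        for n, s, t in zip(mask.shape, mask.spacing_mm, target_spacing_mm)
    ]
    zoom = [ns / n for ns, n in zip(new_shape, mask.shape)]
    out = ndi.zoom(mask.voxels, zoom, order=0, mode="nearest")
    return BinaryMask(out.astype(np.uint8), tuple(target_spacing_mm), mask.origin_mm)


def brain_mask(img: ImageVolume, strategy: str = "none") -> BinaryMask:
    """Pluggable brain-mask step (the field's skull stripping).

    ``none`` returns a full mask; ``threshold`` uses Otsu's threshold plus
    hole closing (sufficient for phantoms, which have no skull);
    ``file:<path>`` loads an externally supplied mask.
    """
    if strategy == "none":
        return BinaryMask(np.ones(img.shape, np.uint8), img.spacing_mm, img.origin_mm)
    if strategy == "threshold":
        from skimage.filters import threshold_otsu

        t = threshold_otsu(np.asarray(img.voxels))
        m = np.asarray(img.voxels) > t
        m = ndi.binary_closing(m, structure=np.ones((3, 3, 3), bool))
        return BinaryMask(m.astype(np.uint8), img.spacing_mm, img.origin_mm)
    if strategy.startswith("file:"):
        return BinaryMask.load(strategy[len("file:") :])
    raise ValueError(f"unknown brain mask strategy {strategy!r}")


def preprocess_volume(
    img: ImageVolume,
    cfg: PreprocessConfig | None = None,
    mask: BinaryMask | None = None,
) -> ImageVolume:
    """Full deterministic pipeline: bias -> resample -> clip/z-score."""
    cfg = cfg or PreprocessConfig()
    out = img
    if cfg.bias_correction:
        m = mask if mask is not None else brain_mask(img, cfg.brain_mask_strategy)
        out = correct_bias(out, m, method=cfg.bias_method)
    out = resample_isotropic(out, cfg.target_spacing_mm)
    return clip_and_standardize(out, cfg)
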