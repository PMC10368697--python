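"""Skeleton-guided 3D patch extraction with exact class-ratio control.

Positive patches are drawn *non-centered* around each aneurysm: the patch
origin is uniform over all origins whose patch fully contains that
aneurysm's mask. Negative patches are centered on vessel-skeleton voxels at
a safety distance from any aneurysm, and are verified aneurysm-free. The
training-set imbalance knob is the exact ratio |negatives| = k * |positives|
with k in 1..5.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import BinaryMask, ImageVolume
from .skeleton import S26, SkeletonVoxelSet


def _case_rng(seed: int, case_id: str, salt: int = 0) -> np.random.Generator:
    """Case-specific generator, independent of cohort ordering."""
    return np.random.default_rng(
        np.random.SeedSequence((seed, zlib.crc32(case_id.encode()), salt))
    )


@dataclass
class PatchSample:
    """Paired image/mask crops with a binary aneurysm label."""

    image_patch: np.ndarray
    mask_patch: np.ndarray
    label: int
    origin_vox: tuple[int, int, int]
    case_id: str = ""

    def __post_init__(self):
        self.image_patch = np.asarray(self.image_patch, np.float32)
        self.mask_patch = np.asarray(self.mask_patch, np.uint8)
        if self.image_patch.shape != self.mask_patch.shape:
            raise ValueError("image/mask patch shapes differ")
        has_pos = bool(self.mask_patch.any())
        if bool(self.label) != has_pos:
            raise ValueError(
                f"label {self.label} inconsistent with mask occupancy {has_pos}"
            )


@dataclass
class SamplingPlan:
    patch_size: tuple[int, int, int] = (64, 64, 64)
    ratio_normal_per_aneurysm: int = 2
    n_positive_per_aneurysm: int = 10
    min_negative_distance_mm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.ratio_normal_per_aneurysm <= 5):
            raise ValueError("ratio must lie in 1..5")
        if self.n_positive_per_aneurysm < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class PatchSet:
    """A sampled cohort of patches plus provenance for case-level splits."""

    samples: list[PatchSample] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def positives(self) -> list[PatchSample]:
        return [s for s in self.samples if s.label == 1]

    @property
    def negatives(self) -> list[PatchSample]:
        return [s for s in self.samples if s.label == 0]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": [s.case_id for s in self.samples],
                "origin_x": [s.origin_vox[0] for s in self.samples],
                "origin_y": [s.origin_vox[1] for s in self.samples],
                "origin_z": [s.origin_vox[2] for s in self.samples],
                "label": [s.label for s in self.samples],
            }
        )

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            out / "patches.npz",
            images=np.stack([s.image_patch for s in self.samples]),
            masks=np.stack([s.mask_patch for s in self.samples]),
        )
        self.manifest().to_csv(out / "manifest.csv", index=False)

    @classmethod
    def load(cls, out_dir: str | Path) -> "PatchSet":
        out = Path(out_dir)
        arrs = np.load(out / "patches.npz")
        man = pd.read_csv(out / "manifest.csv")
        samples = [
            PatchSample(
                arrs["images"][i],
                arrs["masks"][i],
                int(row.label),
                (int(row.origin_x), int(row.origin_y), int(row.origin_z)),
                str(row.case_id),
            )
            for i, row in enumerate(man.itertuples())
        ]
        return cls(samples)


# ---------------------------------------------------------------------------
# cropping with zero padding


def crop_padded(volume: np.ndarray, origin: tuple[int, int, int], size) -> np.ndarray:
    """Crop ``size`` voxels starting at ``origin`` (which may be negative or
    run past the array), zero-padding out-of-bounds regions."""
    size = tuple(size)
    out = np.zeros(size, volume.dtype)
    src = []
    dst = []
    for a in range(3):
        s0 = max(origin[a], 0)
        s1 = min(origin[a] + size[a], volume.shape[a])
        if s0 >= s1:
            return out
        src.append(slice(s0, s1))
        dst.append(slice(s0 - origin[a], s1 - origin[a]))
    out[tuple(dst)] = volume[tuple(src)]
    return out


def admissible_positive_origins(
    component_mask: np.ndarray, patch_size, pad: tuple[int, int, int]
) -> list[tuple[int, int]]:
    """Per-axis [lo, hi] (inclusive) ranges of origins whose patch fully
    contains the component; the admissible set is their box product."""
    idx = np.argwhere(component_mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    ranges = []
    for a in range(3):
        o_lo = max(int(hi[a]) - patch_size[a] + 1, -pad[a])
        o_hi = min(int(lo[a]), component_mask.shape[a] - patch_size[a] + pad[a])
        ranges.append((o_lo, o_hi))
    return ranges


def sample_positive_patches(
    img: ImageVolume,
    aneurysm_mask: BinaryMask,
    plan: SamplingPlan,
    case_id: str = "",
) -> list[PatchSample]:
    """Non-centered positive patches: one batch per 26-connected aneurysm
    component, origins uniform over the set that fully contains it."""
    if aneurysm_mask.is_empty():
        raise ValueError("aneurysm mask is empty; no positive patches to sample")
    ps = tuple(plan.patch_size)
    pad = tuple(p // 2 for p in ps)
    lab, n = ndi.label(aneurysm_mask.astype_bool(), structure=S26)
    rng = _case_rng(plan.seed, case_id, salt=1)
    out: list[PatchSample] = []
    vol = np.asarray(img.voxels)
    msk = aneurysm_mask.voxels
    for comp in range(1, n + 1):
        cm = lab == comp
        idx = np.argwhere(cm)
        extent = idx.max(axis=0) - idx.min(axis=0) + 1
        if (extent > np.array(ps)).any():
            raise ValueError(
                f"aneurysm component {comp} extent {tuple(int(e) for e in extent)} "
                f"exceeds patch size {ps}"
            )
        ranges = admissible_positive_origins(cm, ps, pad)
        for _ in range(plan.n_positive_per_aneurysm):
            origin = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in ranges)
            ip = crop_padded(vol, origin, ps)
            mp = crop_padded(msk, origin, ps)
            out.append(PatchSample(ip, mp, 1, origin, case_id))
    return out


def admissible_negative_centers(
    skeleton: SkeletonVoxelSet,
    aneurysm_mask: BinaryMask,
    min_distance_mm: float,
) -> np.ndarray:
    """Skeleton voxels at >= min_distance_mm from any aneurysm voxel."""
    coords = skeleton.coordinates
    if len(coords) == 0 or aneurysm_mask.is_empty():
        return coords
    dist = ndi.distance_transform_edt(
        ~aneurysm_mask.astype_bool(), sampling=aneurysm_mask.spacing_mm
    )
    keep = dist[tuple(coords.T)] >= min_distance_mm
    return coords[keep]


def sample_negative_patches(
    img: ImageVolume,
    skeleton: SkeletonVoxelSet,
    aneurysm_mask: BinaryMask,
    plan: SamplingPlan,
    n_needed: int,
    case_id: str = "",
) -> list[PatchSample]:
    """Aneurysm-free patches centered on skeleton voxels.

    Candidates pass a physical-distance filter and an explicit crop check
    (distance alone cannot guarantee a clean patch when the patch half-extent
    exceeds the exclusion radius)."""
    if len(skeleton) == 0:
        raise ValueError("skeleton is empty; cannot sample negative patches")
    if n_needed == 0:
        return []
    ps = tuple(plan.patch_size)
    half = tuple(p // 2 for p in ps)
    cand = admissible_negative_centers(skeleton, aneurysm_mask, plan.min_negative_distance_mm)
    rng = _case_rng(plan.seed, case_id, salt=2)
    order = rng.permutation(len(cand))
    vol = np.asarray(img.voxels)
    msk = aneurysm_mask.voxels
    out: list[PatchSample] = []
    for i in order:
        c = cand[i]
        origin = tuple(int(c[a]) - half[a] for a in range(3))
        mp = crop_padded(msk, origin, ps)
        if mp.any():
            continue
        ip = crop_padded(vol, origin, ps)
        out.append(PatchSample(ip, mp, 0, origin, case_id))
        if len(out) == n_needed:
            return out
    warnings.warn(
        f"only {len(out)} admissible negative patches available (requested {n_needed})"
    )
    return out


# ---------------------------------------------------------------------------
# dataset assembly


def build_dataset(
    cases: list[tuple[str, ImageVolume, BinaryMask, SkeletonVoxelSet]],
    plan: SamplingPlan,
    require_positives: bool = True,
) -> PatchSet:
    """Sample a patch cohort with |negatives| = ratio * |positives| exactly.

    ``cases`` are (case_id, image, aneurysm_mask, skeleton) tuples. Sampling
    is per-case seeded (stable under case reordering); the global negative
    quota is distributed round-robin over cases ordered by case_id.
    """
    cases = sorted(cases, key=lambda c: c[0])
    positives: list[PatchSample] = []
    for cid, img, amask, _ in cases:
        if not amask.is_empty():
            positives.extend(sample_positive_patches(img, amask, plan, cid))
    if require_positives and not positives:
        raise ValueError("no positive patches in the entire cohort")

    n_negative = plan.ratio_normal_per_aneurysm * len(positives)
    per_case: dict[str, list[PatchSample]] = {}
    capacity: dict[str, int] = {}
    for cid, img, amask, skel in cases:
        if len(skel) == 0:
            capacity[cid] = 0
            per_case[cid] = []
            continue
        quota_cap = n_negative  # upper bound; trimmed below
        per_case[cid] = sample_negative_patches(img, skel, amask, plan, quota_cap, cid)
        capacity[cid] = len(per_case[cid])

    negatives: list[PatchSample] = []
    cursor = {cid: 0 for cid in per_case}
    ids = [c[0] for c in cases]
    while len(negatives) < n_negative:
        progressed = False
        for cid in ids:
            if len(negatives) == n_negative:
                break
            if cursor[cid] < capacity[cid]:
                negatives.append(per_case[cid][cursor[cid]])
                cursor[cid] += 1
                progressed = True
        if not progressed:
            warnings.warn(
                f"cohort exhausted at {len(negatives)} negatives "
                f"(requested {n_negative}); ratio not met"
            )
            break
    return PatchSet(positives + negatives)


# ---------------------------------------------------------------------------
# augmentation


@dataclass
class AugmentationPolicy:
    """The augmentation suite: flips, zoom, Rician and Gaussian noise,
    rotation, blurring, contrast, and gamma correction.

    Geometric transforms are applied jointly to image (trilinear) and mask
    (nearest-neighbor); intensity transforms touch the image only. Ranges
    are conservative so small aneurysms survive."""

    enabled: tuple[str, ...] = (
        "horizontal_flip",
        "vertical_flip",
        "zoom",
        "rician_noise",
        "gaussian_noise",
        "rotation",
        "blur",
        "contrast",
        "gamma",
    )
    flip_probability: float = 0.5
    zoom_range: tuple[float, float] = (0.9, 1.1)
    rotation_max_deg: float = 15.0
    noise_sigma_range: tuple[float, float] = (0.01, 0.05)  # of intensity range
    blur_sigma_range_vox: tuple[float, float] = (0.3, 0.8)
    contrast_range: tuple[float, float] = (0.9, 1.1)
    gamma_range: tuple[float, float] = (0.8, 1.2)
    max_retries: int = 5
    seed: int = 0


def _zoom_to_shape(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    z = ndi.zoom(arr, factor, order=order, mode="nearest")
    out = np.zeros_like(arr)
    src, dst = [], []
    for a in range(3):
        n, m = arr.shape[a], z.shape[a]
        if m >= n:
            o = (m - n) // 2
            src.append(slice(o, o + n))
            dst.append(slice(0, n))
        else:
            o = (n - m) // 2
            src.append(slice(0, m))
            dst.append(slice(o, o + m))
    out[tuple(dst)] = z[tuple(src)]
    return out


def _apply_transforms(img, msk, policy: AugmentationPolicy, rng):
    on = set(policy.enabled)
    if "horizontal_flip" in on and rng.random() < policy.flip_probability:
        img, msk = img[::-1], msk[::-1]
    if "vertical_flip" in on and rng.random() < policy.flip_probability:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if "rotation" in on:
        axes = [(0, 1), (0, 2), (1, 2)][int(rng.integers(3))]
        angle = float(rng.uniform(-policy.rotation_max_deg, policy.rotation_max_deg))
        img = ndi.rotate(img, angle, axes=axes, reshape=False, order=1, mode="nearest")
        msk = ndi.rotate(msk, angle, axes=axes, reshape=False, order=0, mode="nearest")
    if "zoom" in on:
        f = float(rng.uniform(*policy.zoom_range))
        img = _zoom_to_shape(img, f, order=1)
        msk = _zoom_to_shape(msk, f, order=0)
    if "blur" in on:
        img = ndi.gaussian_filter(img, float(rng.uniform(*policy.blur_sigma_range_vox)))
    rng_range = float(img.max() - img.min()) or 1.0
    if "gaussian_noise" in on:
        s = float(rng.uniform(*policy.noise_sigma_range)) * rng_range
        img = img + rng.normal(0, s, img.shape)
    if "rician_noise" in on:
        s = float(rng.uniform(*policy.noise_sigma_range)) * rng_range
        shift = min(float(img.min()), 0.0)
        mag = img - shift
        img = np.sqrt((mag + rng.normal(0, s, img.shape)) ** 2 + rng.normal(0, s, img.shape) ** 2) + shift
    if "contrast" in on:
        f = float(rng.uniform(*policy.contrast_range))
        mu = float(img.mean())
        img = mu + f * (img - mu)
    if "gamma" in on:
        g = float(rng.uniform(*policy.gamma_range))
        lo, hi = float(img.min()), float(img.max())
        if hi > lo:
            img = ((img - lo) / (hi - lo)) ** g * (hi - lo) + lo
    return np.asarray(img, np.float32), np.asarray(msk, np.uint8)


def augment(sample: PatchSample, policy: AugmentationPolicy) -> PatchSample:
    """Apply the augmentation suite; label is recomputed from the
    transformed mask. If a geometric transform evicts the whole aneurysm
    from a positive patch, parameters are resampled (bounded retries)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(
            (policy.seed, zlib.crc32(sample.case_id.encode()), *map(int, sample.origin_vox), 3)
        )
    )
    for attempt in range(max(policy.max_retries, 1)):
        img, msk = _apply_transforms(
            sample.image_patch.copy(), sample.mask_patch.copy(), policy, rng
        )
        if sample.label == 1 and not msk.any():
            continue
        return replace(sample, image_patch=img, mask_patch=msk, label=int(msk.any()))
    warnings.warn("augmentation evicted the aneurysm repeatedly; passthrough")
    return sample
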