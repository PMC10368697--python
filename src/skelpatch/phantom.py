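"""Synthetic TOF-MRA-like vascular phantoms with known ground truth.

Real cerebral angiograms with expert aneurysm masks are private, so every
downstream stage (preprocessing, skeletonization, patch sampling, training,
evaluation) is exercised on phantoms: bright curved tubes on a dark
background, with ellipsoidal aneurysm bulges attached to vessel walls, a
smooth multiplicative bias field, and Rician magnitude noise — the noise
model of MR magnitude images.

Aneurysm diameters follow the clinical size mix of the cohort the pipeline
targets: overwhelmingly very small (< 5 mm), some small (5–10 mm), rare
large (> 10 mm) lesions, with the full population spanning 1.8–32.6 mm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import make_interp_spline

from .core import BinaryMask, ImageVolume

# clinical strata: (very small, small, large) patient counts 130 : 21 : 3
SIZE_STRATA_COUNTS = (130, 21, 3)
SIZE_STRATA_EDGES_MM = (5.0, 10.0)
DIAMETER_RANGE_MM = (1.8, 32.6)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic angiographic volume."""

    volume_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    n_vessels: int = 3
    vessel_radius_range_mm: tuple[float, float] = (0.5, 3.0)
    n_aneurysms: int = 1
    aneurysm_diameter_range_mm: tuple[float, float] = DIAMETER_RANGE_MM
    vessel_intensity: float = 300.0
    background_intensity: float = 50.0
    rician_sigma: float = 15.0
    bias_amplitude: float = 0.2
    curviness: float = 1.0  # 0 -> straight centerlines
    seed: int = 0

    def validate(self) -> None:
        for name in ("vessel_radius_range_mm", "aneurysm_diameter_range_mm"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lo={lo} > hi={hi}")
        if self.vessel_intensity <= self.background_intensity:
            raise ValueError("vessel_intensity must exceed background_intensity")
        if self.n_vessels < 0 or self.n_aneurysms < 0:
            raise ValueError("counts must be >= 0")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if not (0 <= self.bias_amplitude < 1):
            raise ValueError("bias_amplitude must lie in [0, 1)")
        if self.rician_sigma < 0:
            raise ValueError("rician_sigma must be >= 0")

    def fit_diameter_range_mm(self) -> tuple[float, float]:
        """Diameter range truncated so a bulge can sit inside the volume."""
        lo, hi = self.aneurysm_diameter_range_mm
        extent = min(n * s for n, s in zip(self.volume_shape, self.spacing_mm))
        fit_hi = 0.4 * extent
        if lo > fit_hi:
            raise ValueError(
                f"smallest admissible aneurysm diameter {lo} mm does not fit in a "
                f"volume of minimal extent {extent:.1f} mm (limit {fit_hi:.1f} mm); "
                "enlarge volume_shape or lower aneurysm_diameter_range_mm"
            )
        return lo, min(hi, fit_hi)


@dataclass
class PhantomCase:
    """One phantom with its ground truth."""

    image: ImageVolume
    vessel_mask: BinaryMask
    aneurysm_mask: BinaryMask
    aneurysm_centers: list[tuple[tuple[int, int, int], float]]
    spec: PhantomSpec
    centerline_points_mm: list[np.ndarray] = field(default_factory=list)
    case_id: str = "phantom"


def sample_size_mix(
    n: int,
    seed: int,
    diameter_range_mm: tuple[float, float] = DIAMETER_RANGE_MM,
) -> list[float]:
    """Draw aneurysm diameters from the clinical three-stratum mixture.

    Stratum probabilities are proportional to the 130:21:3 patient counts
    (< 5 mm, 5–10 mm, > 10 mm); within a stratum diameters are uniform on the
    intersection of the stratum with ``diameter_range_mm``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = diameter_range_mm
    e1, e2 = SIZE_STRATA_EDGES_MM
    bounds = [(lo, min(e1, hi)), (max(lo, e1), min(e2, hi)), (max(lo, e2), hi)]
    weights = np.array(
        [c if b[0] < b[1] else 0.0 for c, b in zip(SIZE_STRATA_COUNTS, bounds)],
        dtype=float,
    )
    if weights.sum() == 0:  # degenerate range: single point
        return [float(lo)] * n
    probs = weights / weights.sum()
    strata = rng.choice(3, size=n, p=probs)
    out = []
    for s in strata:
        a, b = bounds[s]
        out.append(float(rng.uniform(a, b)))
    return out


# ---------------------------------------------------------------------------
# geometry helpers


def _random_centerline(rng, shape, spacing, curviness: float) -> np.ndarray:
    """Random smooth curve (mm coords) spanning the volume face-to-face.

    Endpoints are pushed beyond the faces so the stamped tube has no end caps
    inside the volume.
    """
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    axis = int(rng.integers(3))
    start = rng.uniform(0.25, 0.75, 3) * extent
    end = rng.uniform(0.25, 0.75, 3) * extent
    if curviness == 0:  # axis-aligned straight tube
        end = start.copy()
    start[axis] = -0.15 * extent[axis]
    end[axis] = 1.15 * extent[axis]
    k = 4
    t = np.linspace(0, 1, k + 2)
    ctrl = start[None] + t[:, None] * (end - start)[None]
    amp = curviness * 0.12 * extent.min()
    ctrl[1:-1] += rng.uniform(-amp, amp, (k, 3))
    spline = make_interp_spline(t, ctrl, k=3)
    n_samples = max(int(np.linalg.norm(end - start) / (0.5 * min(spacing))), 8)
    return spline(np.linspace(0, 1, n_samples))


def rasterize_tube(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    points_mm: np.ndarray,
    radius_mm: float,
) -> np.ndarray:
    """Rasterize a tube of constant radius around a polyline (bool array).

    Stamps a discrete ball at each densely sampled centerline point; with a
    sampling step well below the voxel size the union is a faithful tube.
    """
    spacing = np.asarray(spacing_mm, float)
    r_vox = radius_mm / spacing
    half = np.ceil(r_vox).astype(int)
    gx, gy, gz = np.mgrid[-half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1]
    ball = (
        (gx * spacing[0]) ** 2 + (gy * spacing[1]) ** 2 + (gz * spacing[2]) ** 2
    ) <= radius_mm**2
    offs = np.argwhere(ball) - half
    out = np.zeros(shape, bool)
    idx = np.round(points_mm / spacing).astype(int)
    idx = np.unique(idx, axis=0)
    all_idx = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    ok = ((all_idx >= 0) & (all_idx < np.array(shape))).all(axis=1)
    all_idx = all_idx[ok]
    out[all_idx[:, 0], all_idx[:, 1], all_idx[:, 2]] = True
    return out


def _rasterize_ellipsoid(shape, spacing, center_mm, semiaxes_mm, rotation) -> np.ndarray:
    spacing = np.asarray(spacing, float)
    r_max = float(max(semiaxes_mm))
    lo = np.maximum(np.floor((center_mm - r_max) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + r_max) / spacing).astype(int) + 1, shape)
    out = np.zeros(shape, bool)
    if (lo >= hi).any():
        return out
    grids = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    pts = grids.reshape(3, -1).T * spacing - center_mm
    local = pts @ rotation  # rotate into ellipsoid frame
    q = (local / np.asarray(semiaxes_mm)) ** 2
    inside = q.sum(axis=1) <= 1.0
    sub = inside.reshape(tuple(hi - lo))
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return out


def _random_rotation(rng) -> np.ndarray:
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    return q * np.sign(np.diag(r))


def _smooth_bias_field(rng, shape, amplitude: float) -> np.ndarray:
    """Random quadratic polynomial field normalized into [1-a, 1+a]."""
    if amplitude == 0:
        return np.ones(shape, np.float32)
    axes = [np.linspace(-1, 1, n) for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x * x, y * y, z * z]
    coefs = rng.uniform(-1, 1, len(terms))
    g = sum(c * t for c, t in zip(coefs, terms))
    g = g - g.mean()
    peak = np.abs(g).max()
    if peak > 0:
        g = g / peak
    return (1.0 + amplitude * g).astype(np.float32)


def _rician(rng, image: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return image
    e1 = rng.normal(0, sigma, image.shape)
    e2 = rng.normal(0, sigma, image.shape)
    return np.sqrt((image + e1) ** 2 + e2**2)


# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom volume with vessel/aneurysm ground truth.

    Deterministic given ``spec.seed``. Vessels are tubes around random cubic
    splines; each aneurysm is a rotated ellipsoid whose center sits on a
    vessel wall; the clean piecewise-constant image is multiplied by a smooth
    bias field and corrupted with Rician noise.
    """
    spec.validate()
    dlo, dhi = spec.fit_diameter_range_mm()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.volume_shape)
    spacing = tuple(spec.spacing_mm)

    vessel = np.zeros(shape, bool)
    centerlines: list[np.ndarray] = []
    radii: list[float] = []
    for _ in range(spec.n_vessels):
        pts = _random_centerline(rng, shape, spacing, spec.curviness)
        r = float(rng.uniform(*spec.vessel_radius_range_mm))
        vessel |= rasterize_tube(shape, spacing, pts, r)
        centerlines.append(pts)
        radii.append(r)

    extent = np.array([n * s for n, s in zip(shape, spacing)])
    diameters = sample_size_mix(spec.n_aneurysms, int(rng.integers(2**31)), (dlo, dhi))
    aneurysm = np.zeros(shape, bool)
    centers: list[tuple[tuple[int, int, int], float]] = []
    for d in diameters:
        placed = False
        for _ in range(50):
            vi = int(rng.integers(len(centerlines))) if centerlines else 0
            if not centerlines:
                break
            pts = centerlines[vi]
            inside = ((pts > d / 2 + 1.0) & (pts < extent - d / 2 - 1.0)).all(axis=1)
            cand = np.nonzero(inside)[0]
            if len(cand) == 0:
                continue
            j = int(cand[rng.integers(len(cand))])
            p = pts[j]
            tang = pts[min(j + 1, len(pts) - 1)] - pts[max(j - 1, 0)]
            tang = tang / (np.linalg.norm(tang) + 1e-9)
            n = rng.standard_normal(3)
            n -= n.dot(tang) * tang
            n /= np.linalg.norm(n) + 1e-9
            center = p + n * 0.8 * radii[vi]  # on the wall, overlapping lumen
            ratios = rng.uniform(0.7, 1.3, 3)
            semi = (d / 2) * ratios / ratios.max()
            rot = _random_rotation(rng)
            bulge = _rasterize_ellipsoid(shape, spacing, center, semi, rot)
            if not bulge.any():
                continue
            aneurysm |= bulge
            cvox = tuple(int(v) for v in np.round(center / np.asarray(spacing)))
            centers.append((cvox, float(d)))
            placed = True
            break
        if not placed and spec.n_aneurysms > 0:
            warnings.warn(f"could not place an aneurysm of diameter {d:.1f} mm")

    fg = vessel | aneurysm
    image = np.full(shape, spec.background_intensity, np.float32)
    image[fg] = spec.vessel_intensity
    image *= _smooth_bias_field(rng, shape, spec.bias_amplitude)
    image = _rician(rng, image, spec.rician_sigma).astype(np.float32)

    return PhantomCase(
        image=ImageVolume(image, spacing),
        vessel_mask=BinaryMask(vessel.astype(np.uint8), spacing),
        aneurysm_mask=BinaryMask(aneurysm.astype(np.uint8), spacing),
        aneurysm_centers=centers,
        spec=spec,
        centerline_points_mm=centerlines,
        case_id=f"phantom-{spec.seed}",
    )


# ---------------------------------------------------------------------------
# persistence


def save_case(case: PhantomCase, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    case.image.save(out / f"{case.case_id}_image.nii.gz")
    case.vessel_mask.save(out / f"{case.case_id}_vessel.nii.gz")
    case.aneurysm_mask.save(out / f"{case.case_id}_aneurysm.nii.gz")
    sidecar = {
        "case_id": case.case_id,
        "aneurysm_centers": [
            {"voxel": list(c), "diameter_mm": d} for c, d in case.aneurysm_centers
        ],
        "spec": asdict(case.spec),
    }
    (out / f"{case.case_id}.json").write_text(json.dumps(sidecar, indent=2))


def load_case(out_dir: str | Path, case_id: str) -> PhantomCase:
    out = Path(out_dir)
    sidecar = json.loads((out / f"{case_id}.json").read_text())
    spec = PhantomSpec(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in sidecar["spec"].items()
        }
    )
    return PhantomCase(
        image=ImageVolume.load(out / f"{case_id}_image.nii.gz"),
        vessel_mask=BinaryMask.load(out / f"{case_id}_vessel.nii.gz"),
        aneurysm_mask=BinaryMask.load(out / f"{case_id}_aneurysm.nii.gz"),
        aneurysm_centers=[
            (tuple(e["voxel"]), e["diameter_mm"]) for e in sidecar["aneurysm_centers"]
        ],
        spec=spec,
        case_id=case_id,
    )
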