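"""Skeletonization steps: thresholding, component filtering, region
growing, closing, and topology-preserving thinning."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.measure import euler_number

from skelpatch.core import BinaryMask, ImageVolume
from skelpatch.skeleton import (
    S26,
    SkeletonConfig,
    binarize_vessels,
    close_holes,
    filter_components,
    is_simple_point,
    region_grow,
    thin_to_skeleton,
)

SPACING = (1.0, 1.0, 1.0)


def _mask(arr):
    return BinaryMask(np.asarray(arr, np.uint8), SPACING)


def _topology(m):
    """Independent global-topology signature: foreground 26-components,
    background 6-components, Euler number."""
    m = np.asarray(m, bool)
    fg = ndi.label(m, structure=S26)[1]
    bg = ndi.label(~m, structure=ndi.generate_binary_structure(3, 1))[1]
    return fg, bg, euler_number(m, connectivity=3)


def _flood_fill_sizes(mask):
    """Independent BFS flood-fill component counter (26-connectivity)."""
    m = np.asarray(mask, bool)
    seen = np.zeros_like(m)
    sizes = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(m & ~seen)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in offsets:
                q = tuple(p[i] + d[i] for i in range(3))
                if all(0 <= q[i] < m.shape[i] for i in range(3)) and m[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        sizes.append(size)
    return sorted(sizes)


class TestBinarize:
    def test_threshold_above_max_gives_empty(self, rng):
        img = ImageVolume(rng.uniform(0, 1, (10, 10, 10)), SPACING)
        with pytest.warns(UserWarning, match="empty"):
            m = binarize_vessels(img, SkeletonConfig(threshold=5.0))
        assert m.is_empty()

    def test_threshold_at_min_gives_full(self, rng):
        img = ImageVolume(rng.uniform(1, 2, (10, 10, 10)), SPACING)
        with pytest.warns(UserWarning, match="full"):
            m = binarize_vessels(img, SkeletonConfig(threshold=0.5))
        assert m.count() == 1000

    def test_midpoint_threshold_recovers_phantom_foreground(self, clean_case, clean_spec):
        thr = 0.5 * (clean_spec.background_intensity + clean_spec.vessel_intensity)
        m = binarize_vessels(clean_case.image, SkeletonConfig(threshold=thr))
        expected = clean_case.vessel_mask.astype_bool() | clean_case.aneurysm_mask.astype_bool()
        assert np.array_equal(m.astype_bool(), expected)


class TestFilterComponents:
    def test_zero_min_is_identity(self, rng):
        m = _mask(rng.uniform(0, 1, (15, 15, 15)) > 0.7)
        assert np.array_equal(filter_components(m, 0).voxels, m.voxels)

    def test_size_threshold(self):
        arr = np.zeros((40, 40, 40), np.uint8)
        arr[1:3, 1:3, 1:3] = 1  # 8 voxels
        arr[10:30, 10:30, 10:23] = 1  # 5200 voxels
        out = filter_components(_mask(arr), 3000)
        assert out.count() == 20 * 20 * 13
        assert out.voxels[1, 1, 1] == 0

    def test_surviving_sizes_vs_flood_fill_oracle(self, rng):
        speckle = rng.uniform(0, 1, (24, 24, 24)) > 0.35
        out = filter_components(_mask(speckle), 50)
        sizes = _flood_fill_sizes(out.astype_bool())
        assert all(s >= 50 for s in sizes)
        # every surviving component was present in the input with same size
        in_sizes = _flood_fill_sizes(speckle)
        assert all(s in in_sizes for s in sizes)


class TestRegionGrow:
    def test_zero_tolerance_is_identity(self):
        img = ImageVolume(np.zeros((10, 10, 10)), SPACING)
        arr = np.zeros((10, 10, 10), np.uint8)
        arr[4:6, 4:6, 4:6] = 1
        out = region_grow(_mask(arr), img, threshold=1.0, tolerance=0.0)
        assert np.array_equal(out.voxels, arr)

    def test_dim_gap_bridged(self):
        """A tube with a one-voxel gap just below threshold is reconnected,
        dropping the 26-component count from 2 to 1."""
        img = np.zeros((30, 5, 5))
        img[2:28, 2, 2] = 100.0
        img[14, 2, 2] = 95.0  # dim voxel below threshold 100, above 90
        vol = ImageVolume(img, SPACING)
        seed = _mask(img >= 100.0)
        assert ndi.label(seed.astype_bool(), structure=S26)[1] == 2
        out = region_grow(seed, vol, threshold=100.0, tolerance=0.10)
        assert ndi.label(out.astype_bool(), structure=S26)[1] == 1

    def test_growth_bounded_by_relaxed_superset(self, rng):
        img = ImageVolume(rng.uniform(0, 1, (20, 20, 20)), SPACING)
        seed = _mask(img.voxels > 0.8)
        out = region_grow(seed, img, threshold=0.8, tolerance=0.1)
        superset = (img.voxels >= 0.8 - 0.1 * 0.8) | seed.astype_bool()
        assert not (out.astype_bool() & ~superset).any()
        assert (out.astype_bool() >= seed.astype_bool()).all()


class TestClosing:
    def test_radius_zero_identity(self, rng):
        m = _mask(rng.uniform(0, 1, (12, 12, 12)) > 0.5)
        assert np.array_equal(close_holes(m, 0).voxels, m.voxels)

    def test_interior_hole_filled(self):
        arr = np.ones((7, 7, 7), np.uint8)
        arr[3, 3, 3] = 0
        out = close_holes(_mask(arr), 1)
        assert out.voxels[3, 3, 3] == 1

    def test_idempotent(self, rng):
        m = _mask(ndi.binary_dilation(rng.uniform(0, 1, (20, 20, 20)) > 0.9))
        once = close_holes(m, 1)
        twice = close_holes(once, 1)
        assert np.array_equal(once.voxels, twice.voxels)


class TestThinning:
    def test_line_unchanged(self):
        arr = np.zeros((3, 3, 30), np.uint8)
        arr[1, 1, 2:28] = 1
        skel = thin_to_skeleton(_mask(arr))
        assert np.array_equal(skel.to_mask().voxels, arr)

    def test_empty(self):
        skel = thin_to_skeleton(_mask(np.zeros((5, 5, 5))))
        assert len(skel) == 0
        assert skel.to_mask().is_empty()

    def test_solid_rod_becomes_single_curve(self):
        arr = np.zeros((9, 9, 54), np.uint8)
        arr[2:7, 2:7, 2:52] = 1
        skel = thin_to_skeleton(_mask(arr))
        s = skel.to_mask().astype_bool()
        assert ndi.label(s, structure=S26)[1] == 1
        # curve length close to the rod length of 50 voxels
        assert abs(len(skel) - 50) <= 10
        # thin: every voxel has at most 2 neighbors (a simple curve)
        nb = ndi.convolve(s.astype(int), np.ones((3, 3, 3), int), mode="constant") - 1
        assert nb[s].max() <= 2

    def test_subset_topology_and_idempotence_on_blobs(self, rng):
        for _ in range(8):
            m = np.zeros((24, 24, 24), bool)
            for _ in range(rng.integers(1, 4)):
                c = rng.integers(4, 20, 3)
                r = int(rng.integers(2, 5))
                g = np.ogrid[:24, :24, :24]
                m |= sum((g[i] - c[i]) ** 2 for i in range(3)) <= r**2
            skel = thin_to_skeleton(_mask(m)).to_mask().astype_bool()
            assert not (skel & ~m).any()  # subset
            assert ndi.label(skel, structure=S26)[1] == ndi.label(m, structure=S26)[1]
            again = thin_to_skeleton(_mask(skel)).to_mask().astype_bool()
            assert np.array_equal(skel, again)  # idempotent


class TestSimplePoint:
    def test_interior_of_line_not_simple(self):
        arr = np.zeros((3, 3, 9), bool)
        arr[1, 1, :] = True
        assert not is_simple_point(arr, (1, 1, 4))

    def test_corner_of_solid_cube_simple(self):
        arr = np.zeros((5, 5, 5), bool)
        arr[1:4, 1:4, 1:4] = True
        assert is_simple_point(arr, (1, 1, 1))

    def test_matches_global_topology_probe(self, rng):
        """Deleting a voxel flagged simple leaves the global topology
        signature unchanged; deleting a non-simple interior-of-curve voxel
        changes it."""
        m = np.zeros((10, 10, 10), bool)
        m[2:8, 2:8, 2:8] = True
        for vox in [(2, 2, 2), (2, 5, 5), (5, 5, 5)]:
            before = _topology(m)
            removed = m.copy()
            removed[vox] = False
            after = _topology(removed)
            if is_simple_point(m, vox):
                assert before == after
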