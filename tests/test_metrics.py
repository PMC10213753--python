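"""Metric contracts: closed-form Dice cases, oracle equivalence of the
Hausdorff and discrete Fréchet implementations, rigid invariances, and the
pseudo-volumetric per-case aggregation rules."""

from functools import lru_cache

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from rectseg.metrics import (
    Contour,
    dice,
    evaluate_case,
    extract_boundary,
    frechet,
    hausdorff,
)

from conftest import random_blob_mask


# --------------------------------------------------------------------------
# independent oracles


def brute_force_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """O(n*m) all-pairs max-min evaluation of the Hausdorff definition."""
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def recursive_frechet(a: np.ndarray, b: np.ndarray) -> float:
    """Memoized textbook recursion for the discrete Fréchet distance."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)

    @lru_cache(maxsize=None)
    def c(i, j):
        d = float(np.hypot(*(a[i] - b[j])))
        if i == 0 and j == 0:
            return d
        if i == 0:
            return max(c(0, j - 1), d)
        if j == 0:
            return max(c(i - 1, 0), d)
        return max(min(c(i - 1, j), c(i - 1, j - 1), c(i, j - 1)), d)

    return c(len(a) - 1, len(b) - 1)


def random_polyline(rng, n_max=50):
    n = int(rng.integers(2, n_max + 1))
    return rng.uniform(-10, 10, (n, 2))


# --------------------------------------------------------------------------
# Dice


class TestDice:
    def test_closed_form_four_six_three(self):
        x = np.zeros(12, dtype=bool)
        y = np.zeros(12, dtype=bool)
        x[:4] = True          # |X| = 4
        y[1:7] = True         # |Y| = 6, |X∩Y| = 3
        assert dice(x, y) == pytest.approx(0.6)

    def test_identity_disjoint_and_empty_conventions(self, rng):
        m = random_blob_mask(rng)
        assert dice(m, m) == 1.0
        other = np.zeros_like(m)
        other[0, 0] = True
        assert dice(m & ~m | other, np.roll(other, 5, axis=0)) == 0.0
        assert dice(np.zeros_like(m), np.zeros_like(m)) == 1.0
        assert dice(m, np.zeros_like(m)) == 0.0

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            a, b = random_blob_mask(rng), random_blob_mask(rng)
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3)), np.zeros((4, 4)))


# --------------------------------------------------------------------------
# boundary extraction


class TestExtractBoundary:
    def test_square_perimeter(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True  # 10 px side
        contours = extract_boundary(mask, (1.0, 1.0))
        assert len(contours) == 1
        c = contours[0]
        assert c.closed
        assert c.perimeter == pytest.approx(40.0, abs=2.0)

    def test_empty_mask(self):
        assert extract_boundary(np.zeros((10, 10)), (1, 1)) == []

    def test_translation_equivariance(self, rng):
        mask = random_blob_mask(rng, shape=(40, 40), n_blobs=1)
        shifted = np.roll(mask, 5, axis=0)
        a = extract_boundary(mask, (2.0, 1.0))[0]
        b = extract_boundary(shifted, (2.0, 1.0))[0]
        np.testing.assert_allclose(b.points, a.points + [5 * 2.0, 0.0], atol=1e-9)

    def test_contours_ordered_by_area_and_scaled(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:6, 2:6] = True     # small
        mask[10:30, 10:30] = True  # large
        contours = extract_boundary(mask, (0.5, 0.5))
        assert len(contours) == 2
        assert contours[0].area > contours[1].area
        assert contours[0].area == pytest.approx(20 * 20 * 0.25, rel=0.15)


# --------------------------------------------------------------------------
# Hausdorff


class TestHausdorff:
    def test_identical_contours_zero(self, rng):
        c = extract_boundary(random_blob_mask(rng), (1, 1))[0]
        assert hausdorff(c, c) == 0.0

    def test_matches_brute_force_oracle_on_random_contours(self, rng):
        for _ in range(100):
            a = extract_boundary(random_blob_mask(rng, n_blobs=2), (0.781, 0.781))
            b = extract_boundary(random_blob_mask(rng, n_blobs=2), (0.781, 0.781))
            if not a or not b:
                continue
            pa, pb = a[0].points[:500], b[0].points[:500]
            assert hausdorff(Contour(pa, closed=False), Contour(pb, closed=False)) == \
                pytest.approx(brute_force_hausdorff(pa, pb), abs=1e-12)

    def test_symmetry_and_translation(self, rng):
        a = random_polyline(rng, 30)
        b = random_polyline(rng, 30)
        assert hausdorff(a, b) == hausdorff(b, a)
        shift = np.array([3.0, 0.0])
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert hausdorff(sq, sq + shift) == pytest.approx(
            brute_force_hausdorff(sq, sq + shift)
        )

    def test_empty_contour_rejected(self):
        with pytest.raises(ValueError):
            hausdorff(np.zeros((0, 2)), np.ones((3, 2)))


# --------------------------------------------------------------------------
# Fréchet


class TestFrechet:
    def test_identical_zero(self, rng):
        c = extract_boundary(random_blob_mask(rng), (1, 1))[0]
        assert frechet(c, c) == 0.0

    def test_parallel_segments_closed_form(self):
        p = np.array([[0.0, 0.0], [1.0, 0.0]])
        q = np.array([[0.0, 1.0], [1.0, 1.0]])
        assert frechet(p, q) == pytest.approx(1.0)

    def test_matches_recursive_oracle_on_open_polylines(self, rng):
        for _ in range(100):
            a, b = random_polyline(rng), random_polyline(rng)
            assert frechet(a, b) == pytest.approx(recursive_frechet(a, b), abs=1e-12)

    def test_frechet_at_least_hausdorff(self, rng):
        for _ in range(50):
            a, b = random_polyline(rng), random_polyline(rng)
            assert frechet(a, b) >= hausdorff(a, b) - 1e-12

    def test_closed_contour_start_shift_invariance(self, rng):
        c = extract_boundary(random_blob_mask(rng, n_blobs=1), (1, 1))[0]
        rolled = Contour(np.roll(c.points, len(c) // 3, axis=0), closed=True)
        assert frechet(c, rolled) == pytest.approx(0.0, abs=0.35)
        assert frechet(c, rolled, exact_shifts=True) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self, rng):
        a, b = random_polyline(rng, 30), random_polyline(rng, 30)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        t = np.array([5.0, -2.0])
        fa, ha = frechet(a, b), hausdorff(a, b)
        fb, hb = frechet(a @ rot.T + t, b @ rot.T + t), hausdorff(a @ rot.T + t, b @ rot.T + t)
        assert fb == pytest.approx(fa, abs=1e-9)
        assert hb == pytest.approx(ha, abs=1e-9)


# --------------------------------------------------------------------------
# per-case evaluation


class TestEvaluateCase:
    def _volume(self, rng, nz=4):
        vol = np.zeros((40, 40, nz), dtype=bool)
        for z in range(nz):
            vol[:, :, z] = random_blob_mask(rng, shape=(40, 40), n_blobs=1)
        return vol

    def test_perfect_agreement(self, rng):
        vol = self._volume(rng)
        rec = evaluate_case(vol, vol, (0.781, 0.781, 4.0), region="wall", case_id="c0")
        assert rec.dice == 1.0
        assert rec.hausdorff == 0.0
        assert rec.frechet == 0.0
        assert rec.n_slices_evaluated == vol.shape[2]

    def test_one_voxel_dilation_gives_spacing_hausdorff(self):
        vol = np.zeros((40, 40, 2), dtype=bool)
        yy, xx = np.mgrid[:40, :40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 < 8**2
        vol[:, :, 0] = vol[:, :, 1] = disk
        struct = ndimage.generate_binary_structure(2, 1)
        dilated = vol.copy()
        for z in range(2):
            dilated[:, :, z] = ndimage.binary_dilation(vol[:, :, z], struct)
        rec = evaluate_case(dilated, vol, (0.781, 0.781, 4.0))
        assert rec.dice < 1.0
        assert rec.hausdorff == pytest.approx(0.781, abs=0.25)

    def test_empty_slice_exclusion_rule(self, rng):
        vol = self._volume(rng, nz=6)
        pred = vol.copy()
        pred[:, :, 3:] = False  # empty on half the slices
        rec = evaluate_case(pred, vol, (1, 1, 4))
        assert rec.n_slices_evaluated == 3
        assert rec.dice < 1.0  # empty slices still count in 3D Dice

    def test_voxel_units(self, rng):
        vol = self._volume(rng, nz=2)
        rec_mm = evaluate_case(vol, np.roll(vol, 2, axis=0), (0.5, 0.5, 4.0), units="mm")
        rec_vox = evaluate_case(vol, np.roll(vol, 2, axis=0), (0.5, 0.5, 4.0), units="voxel")
        assert rec_mm.hausdorff == pytest.approx(0.5 * rec_vox.hausdorff, rel=1e-6)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_case(np.zeros((4, 4, 2)), np.zeros((4, 4, 3)), (1, 1, 1))
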