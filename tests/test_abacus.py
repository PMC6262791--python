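"""Unit and property tests for the 3D nuclear-counting pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opticmorph.abacus import (
    AbacusParams,
    CentroidSet,
    VoxelGrid,
    count_in_roi,
    extended_maxima,
    find_nuclei,
    rescale_hi_lo,
    smooth_anisotropic,
)
from opticmorph import synthetic

from .conftest import SCENE_PARAMS
from .oracles import bf_extended_maxima, labels_to_components


def grid_of(data, dx=1.0, dz=1.0, bit_depth=8):
    return VoxelGrid(np.asarray(data), dx, dz, bit_depth)


class TestRescaleHiLo:
    def test_background_maps_to_zero(self):
        g = grid_of(np.full((4, 5, 6), 30, dtype=np.uint8))
        out = rescale_hi_lo(g, background=30, ceiling=200)
        assert (out.data == 0).all()

    def test_full_range_maps_just_below_max(self):
        data = np.zeros((2, 3, 3), dtype=np.uint8)
        data[0, 0, 0] = 255
        data[0, 0, 1] = 128
        out = rescale_hi_lo(grid_of(data), background=0, ceiling=255)
        assert out.data.max() == 254  # brightest pixel just below 255
        assert out.data[0, 0, 1] == int(128 * 254 / 255)

    def test_hand_computed_linear_map(self):
        # (50 - 10) * 254 / 120 = 84.67 -> 84 under floor rounding
        data = np.array([[[10, 50, 130]]], dtype=np.uint8)
        out = rescale_hi_lo(grid_of(data), background=10, ceiling=130)
        assert out.data.ravel().tolist() == [0, 84, 254]

    def test_clipping_below_and_above(self):
        data = np.array([[[5, 10, 200, 255]]], dtype=np.uint8)
        out = rescale_hi_lo(grid_of(data), background=10, ceiling=200)
        assert out.data.ravel()[0] == 0
        assert out.data.ravel()[-1] == 254

    def test_invalid_anchors_rejected(self):
        g = grid_of(np.zeros((2, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError):
            rescale_hi_lo(g, background=100, ceiling=100)
        with pytest.raises(ValueError):
            rescale_hi_lo(g, background=0, ceiling=300)


class TestSmoothAnisotropic:
    def test_sigma_z_formula(self):
        g = grid_of(np.zeros((4, 4, 4), dtype=np.uint8), dx=0.7, dz=2.1)
        assert g.sigma_z_for(3.0) == pytest.approx(1.0)

    def test_uniform_grid_is_fixed_point(self):
        g = grid_of(np.full((8, 8, 8), 77, dtype=np.uint8))
        out = smooth_anisotropic(g, sigma_xy=2.0)
        assert np.allclose(out.data, 77)

    def test_impulse_second_moments_and_mass(self):
        data = np.zeros((41, 61, 61))
        data[20, 30, 30] = 255.0
        g = VoxelGrid(data, dx=0.7, dz=2.1)
        sigma_xy = 3.0
        out = smooth_anisotropic(g, sigma_xy).data
        # total intensity conserved (reflect boundary, interior impulse)
        assert out.sum() == pytest.approx(255.0, rel=1e-3)
        zz, yy, xx = np.mgrid[0:41, 0:61, 0:61].astype(float)
        m = out / out.sum()
        var_x = (m * (xx - 30) ** 2).sum()
        var_y = (m * (yy - 30) ** 2).sum()
        var_z = (m * (zz - 20) ** 2).sum()
        assert var_x == pytest.approx(sigma_xy**2, rel=0.01)
        assert var_y == pytest.approx(sigma_xy**2, rel=0.01)
        assert var_z == pytest.approx(g.sigma_z_for(sigma_xy) ** 2, rel=0.01)


class TestExtendedMaxima:
    def test_two_peaks_with_shallow_saddle_merge(self):
        # profile along x: peaks 10 and 9 around a saddle at 8
        profile = np.array([2, 5, 10, 8, 9, 5, 2], dtype=float)
        img = np.zeros((3, 3, 7))
        img[1, 1, :] = profile
        # secondary peak dynamic is 1 (9 - 8): h=2 suppresses it
        assert len(labels_to_components(extended_maxima(img, h=2))) == 1
        assert len(labels_to_components(extended_maxima(img, h=0.5))) == 2
        # oracle agrees on both
        for h in (2, 0.5):
            assert labels_to_components(extended_maxima(img, h)) == \
                bf_extended_maxima(img, h, 26)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bruteforce_on_random_grids(self, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(30):
            shape = rng.integers(3, 8, size=3)
            img = rng.integers(0, 21, size=shape).astype(float)
            h = float(rng.integers(1, 7))
            mine = labels_to_components(extended_maxima(img, h, connectivity))
            assert mine == bf_extended_maxima(img, h, connectivity)


class TestFindNuclei:
    def test_single_planted_blob(self):
        truth = synthetic.SyntheticVolumeTruth(
            (synthetic.NucleusSpec((20 * 0.692, 20 * 0.692, 10 * 2.1), 1.8, 200.0),),
            seed=0,
        )
        grid = synthetic.make_nuclei_volume(truth, (20, 40, 40))["green"]
        found = find_nuclei(grid, SCENE_PARAMS)
        assert found.count == 1
        planted = np.array(truth.nuclei[0].center)
        err = np.abs(found.points[0] - planted)
        assert err[0] <= grid.dx and err[1] <= grid.dx and err[2] <= grid.dz

    def test_unresolvably_close_pair_counts_once(self):
        # two equal blobs separated by < 2 sigma: their sum is unimodal
        sigma = 1.8
        c1 = np.array([12.0, 12.0, 10.0])
        c2 = c1 + np.array([1.5 * sigma, 0, 0])
        truth = synthetic.SyntheticVolumeTruth(
            tuple(synthetic.NucleusSpec(tuple(c), sigma, 200.0) for c in (c1, c2)),
            dx=0.692, dz=2.1, seed=0,
        )
        grid = synthetic.make_nuclei_volume(truth, (16, 48, 48))["green"]
        assert find_nuclei(grid, SCENE_PARAMS).count == 1

    def test_well_separated_pair_counts_twice(self):
        sigma = 1.8
        c1 = np.array([10.0, 12.0, 10.0])
        c2 = c1 + np.array([8 * sigma, 0, 0])
        truth = synthetic.SyntheticVolumeTruth(
            tuple(synthetic.NucleusSpec(tuple(c), sigma, 200.0) for c in (c1, c2)),
            dx=0.692, dz=2.1, seed=0,
        )
        grid = synthetic.make_nuclei_volume(truth, (16, 64, 64))["green"]
        assert find_nuclei(grid, SCENE_PARAMS).count == 2

    def test_recovers_planted_count(self, small_volume):
        assert find_nuclei(small_volume, SCENE_PARAMS).count == 50

    def test_empty_after_threshold_is_empty_result(self):
        g = grid_of(np.full((6, 6, 6), 3, dtype=np.uint8))
        out = find_nuclei(g, AbacusParams(sigma_xy=1.0, L=50, h=5))
        assert out.count == 0

    def test_h_above_dynamic_range_warns_and_returns_empty(self):
        data = np.zeros((8, 12, 12), dtype=np.uint8)
        data[4, 6, 6] = 40
        g = grid_of(data)
        with pytest.warns(UserWarning, match="dynamic range"):
            out = find_nuclei(g, AbacusParams(sigma_xy=1.0, L=0, h=200))
        assert out.count == 0

    def test_count_monotone_in_h(self, small_volume):
        counts = [
            find_nuclei(small_volume, AbacusParams(2.0, 20.0, h)).count
            for h in (5, 15, 30, 60, 90)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_count_monotone_in_L(self, small_volume):
        counts = [
            find_nuclei(small_volume, AbacusParams(2.0, L, 30.0)).count
            for L in (5, 20, 50, 80, 100)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_spacing_equivariance(self):
        """The same physical scene sampled at two z-steps gives one count."""
        placed = synthetic.random_well_separated_nuclei(
            12, (40, 96, 96), dz=1.05, seed=3
        )
        fine = synthetic.SyntheticVolumeTruth(placed.nuclei, 0.692, 1.05, 0.0, 3)
        coarse = synthetic.SyntheticVolumeTruth(placed.nuclei, 0.692, 2.1, 0.0, 3)
        g_fine = synthetic.make_nuclei_volume(fine, (40, 96, 96))["green"]
        g_coarse = synthetic.make_nuclei_volume(coarse, (20, 96, 96))["green"]
        assert g_fine.sigma_z_for(2.0) == pytest.approx(2 * g_coarse.sigma_z_for(2.0))
        assert find_nuclei(g_fine, SCENE_PARAMS).count == 12
        assert find_nuclei(g_coarse, SCENE_PARAMS).count == 12


class TestCountInRoi:
    def make_centroids(self, points, shape=(10, 10, 10), dx=1.0, dz=1.0):
        return CentroidSet(points, np.full(len(points), 99.0), shape, dx, dz)

    def test_whole_volume_roi_counts_all(self, small_volume):
        found = find_nuclei(small_volume, SCENE_PARAMS)
        roi = np.ones(small_volume.shape, dtype=bool)
        assert count_in_roi(found, roi) == found.count

    def test_empty_roi_counts_none(self, small_volume):
        found = find_nuclei(small_volume, SCENE_PARAMS)
        assert count_in_roi(found, np.zeros(small_volume.shape, bool)) == 0

    def test_partial_roi_counts_planted_subset(self):
        pts = np.column_stack([np.arange(10) + 0.2, np.full(10, 5.0), np.full(10, 5.0)])
        cs = self.make_centroids(pts)
        roi = np.zeros((10, 10, 10), dtype=bool)
        roi[:, :, :4] = True  # x voxels 0..3 capture planted x = 0.2..3.2
        assert count_in_roi(cs, roi) == 4

    def test_shape_mismatch_rejected(self):
        cs = self.make_centroids(np.array([[1.0, 1.0, 1.0]]))
        with pytest.raises(ValueError, match="shape"):
            count_in_roi(cs, np.ones((3, 3, 3), bool))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    h1=st.integers(1, 5),
    dh=st.integers(1, 6),
)
def test_h_monotonicity_property(seed, h1, dh):
    """Raising the minimum peak height never increases the maxima count."""
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 30, size=(5, 6, 6)).astype(float)
    n1 = len(labels_to_components(extended_maxima(img, h1)))
    n2 = len(labels_to_components(extended_maxima(img, h1 + dh)))
    assert n2 <= n1
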