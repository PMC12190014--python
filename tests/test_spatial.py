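"""Core/margin VOI geometry and the core-to-margin uptake statistic."""

import math

import numpy as np
import pytest

from cd4pet.errors import (
    DegenerateCoreError,
    EmptyRegionError,
    InvalidParameterError,
)
from cd4pet.radiometrics import ActivityVolume, InjectionContext
from cd4pet.spatial import (
    RegionMask,
    central_axial_slice,
    core_margin_ratio,
    derive_core_margin,
    mask_centroid,
    region_mean_uptake,
)

from conftest import disk_mask, ellipse_mask


def pullback_oracle(grid, scale):
    """Brute-force per-pixel pull-back rasterization (loop form)."""
    com = np.array(
        [
            np.average(np.argwhere(grid)[:, a])
            for a in range(grid.ndim)
        ]
    )
    core = np.zeros_like(grid)
    for idx in np.ndindex(grid.shape):
        mapped = com + (np.array(idx) - com) / scale
        mapped = np.rint(mapped).astype(int)
        if all(0 <= m < s for m, s in zip(mapped, grid.shape)):
            core[idx] = grid[tuple(mapped)]
    return core


class TestMaskCentroid:
    def test_symmetric_cube_center(self):
        grid = np.zeros((9, 9, 9), dtype=bool)
        grid[3:6, 3:6, 3:6] = True
        mask = RegionMask(grid, spacing=(1.0, 2.0, 0.5))
        assert mask_centroid(mask) == pytest.approx([4.0, 8.0, 2.0])

    def test_single_and_two_voxels(self):
        grid = np.zeros((5, 5, 5), dtype=bool)
        grid[1, 2, 3] = True
        mask = RegionMask(grid, spacing=(1.0, 1.0, 1.0))
        assert mask_centroid(mask) == pytest.approx([1.0, 2.0, 3.0])
        grid[3, 2, 3] = True
        assert mask_centroid(RegionMask(grid)) == pytest.approx([2.0, 2.0, 3.0])

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            mask_centroid(RegionMask(np.zeros((4, 4), dtype=bool)))


class TestCentralAxialSlice:
    def test_sphere_center_slice(self):
        grid = np.zeros((31, 31, 31), dtype=bool)
        ii, jj, kk = np.indices(grid.shape)
        grid[(ii - 15) ** 2 + (jj - 15) ** 2 + (kk - 15) ** 2 <= 25] = True
        # sphere spanning slices 10-20 -> 15
        assert central_axial_slice(RegionMask(grid)) == 15

    def test_single_slice_mask(self):
        grid = np.zeros((10, 8, 8), dtype=bool)
        grid[4, 2:5, 2:5] = True
        assert central_axial_slice(RegionMask(grid)) == 4

    def test_hemisphere_matches_area_weighting_oracle(self):
        grid = np.zeros((30, 40, 40), dtype=bool)
        ii, jj, kk = np.indices(grid.shape)
        sphere = (ii - 15) ** 2 + (jj - 20) ** 2 + (kk - 20) ** 2 <= 100
        grid = sphere & (ii <= 15)  # lower hemisphere, slices 5-15
        areas = grid.sum(axis=(1, 2))
        oracle = int(round(np.average(np.arange(30), weights=areas)))
        assert central_axial_slice(RegionMask(grid)) == oracle


class TestDeriveCoreMargin:
    def test_disk_core_is_quarter_area(self):
        tumor = disk_mask(128, 50.0)
        core, margin = derive_core_margin(tumor, scale=0.5)
        assert core.size / tumor.size == pytest.approx(0.25, rel=0.02)
        assert not np.any(core.grid & margin.grid)
        assert np.array_equal(core.grid | margin.grid, tumor.grid)

    def test_scale_to_one_limit(self):
        tumor = disk_mask(64, 25.0)
        core, _ = derive_core_margin(tumor, scale=0.999)
        assert core.size / tumor.size > 0.99

    @pytest.mark.parametrize("spacing", [(1.0, 1.0), (0.5, 2.0)])
    def test_ellipse_matches_bruteforce_pullback(self, spacing):
        tumor = ellipse_mask((61, 61), (20.0 * spacing[0], 10.0 * spacing[1]),
                             spacing=spacing)
        core, _ = derive_core_margin(tumor, scale=0.5)
        oracle = pullback_oracle(tumor.grid, 0.5)
        assert np.array_equal(core.grid, oracle)

    def test_slice2d_restricts_to_central_slice(self):
        grid = np.zeros((21, 41, 41), dtype=bool)
        ii, jj, kk = np.indices(grid.shape, dtype=float)
        grid = (ii - 10) ** 2 + (jj - 20) ** 2 + (kk - 20) ** 2 <= 15**2
        tumor = RegionMask(grid)
        core, margin = derive_core_margin(tumor, mode="slice2d")
        analysed = core.grid | margin.grid
        assert np.array_equal(analysed, np.where(
            np.arange(21)[:, None, None] == 10, grid, False))
        assert core.slice_index == 10

    def test_degenerate_core_raises(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[2, 2] = True
        grid[2, 3] = True
        with pytest.raises(DegenerateCoreError):
            derive_core_margin(RegionMask(grid), scale=0.3)

    def test_invalid_scale_rejected(self):
        tumor = disk_mask(32, 10.0)
        for bad in (0.0, 1.0, 1.5, -0.2):
            with pytest.raises(InvalidParameterError):
                derive_core_margin(tumor, scale=bad)


class TestRegionMeanUptake:
    def test_uniform_field_with_decay(self, ctx):
        vol = ActivityVolume(np.full((8, 8, 8), 2000.0), scan_time=12.7)
        region = RegionMask(np.ones((8, 8, 8), dtype=bool))
        # one half-life elapsed doubles the concentration back to injection
        assert region_mean_uptake(vol, region, ctx) == pytest.approx(
            100.0 * 4000.0 / 1e7
        )

    def test_mean_linearity(self, ctx):
        voxels = np.zeros((4, 4, 4))
        region = np.zeros((4, 4, 4), dtype=bool)
        region[:2] = True
        voxels[0] = 0.0
        voxels[1] = 2000.0
        vol = ActivityVolume(voxels, scan_time=0.0)
        uniform = ActivityVolume(np.full((4, 4, 4), 1000.0), scan_time=0.0)
        mask = RegionMask(region)
        assert region_mean_uptake(vol, mask, ctx) == pytest.approx(
            region_mean_uptake(uniform, mask, ctx)
        )

    def test_matches_bruteforce_voxel_loop(self, rng, ctx):
        voxels = rng.uniform(0, 5000, size=(10, 10, 10))
        grid = rng.random((10, 10, 10)) < 0.3
        grid[0, 0, 0] = True
        vol = ActivityVolume(voxels, scan_time=3.0)
        total, n = 0.0, 0
        for idx in np.ndindex(grid.shape):
            if grid[idx]:
                total += voxels[idx]
                n += 1
        expected = (total / n) * 2 ** (3.0 / 12.7) * 100.0 / 1e7
        assert region_mean_uptake(vol, RegionMask(grid), ctx) == pytest.approx(
            expected
        )

    def test_empty_region_raises(self, ctx):
        vol = ActivityVolume(np.zeros((4, 4, 4)))
        with pytest.raises(EmptyRegionError):
            region_mean_uptake(vol, RegionMask(np.zeros((4, 4, 4), dtype=bool)), ctx)


class TestCoreMarginRatio:
    @pytest.mark.parametrize(
        "core, margin, expected",
        [(0.4, 0.4, 1.0), (0.6, 0.3, 2.0), (0.0, 0.3, 0.0)],
    )
    def test_examples(self, core, margin, expected):
        assert core_margin_ratio(core, margin).ratio == pytest.approx(expected)

    def test_zero_margin_flagged(self):
        score = core_margin_ratio(0.5, 0.0)
        assert score.undefined_ratio and math.isnan(score.ratio)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            core_margin_ratio(-0.1, 0.5)

    def test_monotone_in_core_intensity(self):
        ratios = [core_margin_ratio(c, 0.3).ratio for c in (0.3, 0.4, 0.5, 0.9)]
        assert ratios == sorted(ratios) and len(set(ratios)) == len(ratios)


class TestPartitionIdentity:
    def test_weighted_means_recompose_tumor_mean(self, rng, ctx):
        for _ in range(10):
            voxels = rng.uniform(0, 4000, size=(20, 20, 20))
            ii, jj, kk = np.indices((20, 20, 20), dtype=float)
            c = rng.uniform(8, 11, size=3)
            r = rng.uniform(4, 7)
            grid = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2 <= r**2
            tumor = RegionMask(grid)
            vol = ActivityVolume(voxels, scan_time=1.0)
            core, margin = derive_core_margin(tumor, mode="volume3d")
            tm = region_mean_uptake(vol, tumor, ctx)
            cm = region_mean_uptake(vol, core, ctx)
            mm = region_mean_uptake(vol, margin, ctx)
            recomposed = (core.size * cm + margin.size * mm) / tumor.size
            assert recomposed == pytest.approx(tm, rel=1e-12)
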