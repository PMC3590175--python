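import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restalff.coords import make_affine
from restalff.fc import (
    extract_seed_series,
    fc_map_subject,
    fc_z_map,
    fisher_z,
    group_fc_maps,
    inverse_fisher_z,
    peak_difference_voxel,
    regress_out_nuisance,
    resolve_sphere,
)
from restalff.group_stats import StatMap


@pytest.fixture
def grid():
    shape = (11, 11, 9)
    return shape, np.ones(shape, dtype=bool), make_affine(shape, 3.0)


class TestResolveSphere:
    def test_six_mm_diameter_on_voxel_center_gives_single_voxel(self, grid):
        # radius 3 mm on a 3 mm grid: the centre voxel plus the 6 face
        # neighbours sit exactly at distance 0 and 3 mm (inclusive)
        shape, mask, affine = grid
        center = affine[:3, :3] @ [5, 5, 4] + affine[:3, 3]
        roi = resolve_sphere(center, 6.0, mask, affine)
        assert len(roi) == 7

    def test_diameter_zero_gives_nearest_voxel(self, grid):
        shape, mask, affine = grid
        center = affine[:3, :3] @ [3, 4, 2] + affine[:3, 3]
        roi = resolve_sphere(center, 0.0, mask, affine)
        assert len(roi) == 1 and tuple(roi.voxels[0]) == (3, 4, 2)

    def test_matches_brute_force_distance_scan(self, grid):
        shape, mask, affine = grid
        center = np.array([4.0, -2.5, 1.0])
        roi = resolve_sphere(center, 10.0, mask, affine)
        expected = set()
        for idx in np.argwhere(mask):
            world = affine[:3, :3] @ idx + affine[:3, 3]
            if np.linalg.norm(world - center) <= 5.0 + 1e-9:
                expected.add(tuple(idx))
        assert {tuple(v) for v in roi.voxels} == expected

    def test_empty_resolution_rejected_with_center_in_message(self, grid):
        shape, mask, affine = grid
        empty = np.zeros(shape, dtype=bool)
        with pytest.raises(ValueError, match="100"):
            resolve_sphere((100.0, 0.0, 0.0), 6.0, empty, affine)


class TestPeakDifferenceVoxel:
    def _stat(self, t, affine):
        return StatMap(t_values=t, df=30, mask=np.ones(t.shape, bool), affine=affine)

    def test_unique_maximum_found(self, grid):
        shape, mask, affine = grid
        t = np.zeros(shape)
        t[2, 3, 4] = -7.0  # largest |t|
        t[5, 5, 5] = 4.0
        region = np.argwhere(mask)
        peak = peak_difference_voxel(self._stat(t, affine), region)
        np.testing.assert_allclose(peak, affine[:3, :3] @ [2, 3, 4] + affine[:3, 3])

    def test_tie_breaks_to_lexicographically_smallest(self, grid):
        shape, mask, affine = grid
        t = np.zeros(shape)
        t[6, 1, 1] = t[2, 8, 8] = 5.0
        peak = peak_difference_voxel(self._stat(t, affine), np.argwhere(mask))
        np.testing.assert_allclose(peak, affine[:3, :3] @ [2, 8, 8] + affine[:3, 3])

    def test_matches_enumeration_oracle(self, grid):
        shape, mask, affine = grid
        rng = np.random.default_rng(4)
        t = rng.standard_normal(shape)
        region = np.argwhere(mask)[::3]
        best = max(map(tuple, region), key=lambda v: abs(t[v]))
        peak = peak_difference_voxel(self._stat(t, affine), region)
        np.testing.assert_allclose(peak, affine[:3, :3] @ np.array(best) + affine[:3, 3])

    def test_empty_region_rejected(self, grid):
        shape, mask, affine = grid
        with pytest.raises(ValueError):
            peak_difference_voxel(self._stat(np.zeros(shape), affine),
                                  np.empty((0, 3), dtype=int))


class TestExtractSeedSeries:
    def test_single_voxel_roi_returns_that_series(self, grid, rng):
        shape, mask, affine = grid
        data = rng.standard_normal(shape + (20,))
        roi = resolve_sphere(affine[:3, :3] @ [2, 2, 2] + affine[:3, 3], 0.0, mask, affine)
        np.testing.assert_array_equal(extract_seed_series(data, roi), data[2, 2, 2])

    def test_mean_matches_enumeration(self, grid, rng):
        shape, mask, affine = grid
        data = rng.standard_normal(shape + (15,))
        roi = resolve_sphere((0.0, 0.0, 0.0), 6.0, mask, affine)
        expected = np.mean([data[tuple(v)] for v in roi.voxels], axis=0)
        np.testing.assert_allclose(extract_seed_series(data, roi), expected, atol=1e-12)


class TestRegressOutNuisance:
    def test_zero_motion_reduces_to_demeaning(self, rng):
        series = rng.standard_normal((4, 30))
        with pytest.warns(UserWarning):  # constant columns are dropped
            out = regress_out_nuisance(series, np.zeros((30, 6)))
        np.testing.assert_allclose(out, series - series.mean(axis=-1, keepdims=True),
                                   atol=1e-10)

    def test_series_equal_to_motion_column_is_annihilated(self, rng):
        motion = rng.standard_normal((40, 6))
        out = regress_out_nuisance(motion[:, 2].copy(), motion)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        series = rng.standard_normal((5, 20))
        motion = rng.standard_normal((20, 6))
        design = np.column_stack([np.ones(20), motion])
        beta = np.linalg.solve(design.T @ design, design.T @ series.T)
        expected = series - (design @ beta).T
        np.testing.assert_allclose(regress_out_nuisance(series, motion), expected,
                                   atol=1e-9)

    def test_residuals_orthogonal_to_design(self, rng):
        series = rng.standard_normal((3, 50))
        motion = rng.standard_normal((50, 6))
        out = regress_out_nuisance(series, motion)
        design = np.column_stack([np.ones(50), motion])
        np.testing.assert_allclose(out @ design, 0.0, atol=1e-8)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            regress_out_nuisance(rng.standard_normal((2, 30)), np.zeros((25, 6)))

    def test_seed_averaging_commutes_with_regression(self, grid, rng):
        # regress(mean over ROI) == mean over ROI of regressed voxels
        shape, mask, affine = grid
        data = rng.standard_normal(shape + (30,))
        motion = rng.standard_normal((30, 6))
        roi = resolve_sphere((0.0, 0.0, 0.0), 6.0, mask, affine)
        a = regress_out_nuisance(extract_seed_series(data, roi), motion)
        resid = regress_out_nuisance(data[tuple(roi.voxels.T)], motion)
        np.testing.assert_allclose(a, resid.mean(axis=0), atol=1e-10)


class TestFcMapSubject:
    def test_perfect_and_anti_correlation(self, rng):
        shape = (4, 4, 3)
        mask = np.ones(shape, dtype=bool)
        seed = rng.standard_normal(40)
        data = rng.standard_normal(shape + (40,))
        data[1, 1, 1] = 2.5 * seed
        data[2, 2, 2] = -0.7 * seed
        fc = fc_map_subject(seed, data, mask)
        assert fc.values[1, 1, 1] == pytest.approx(1.0, abs=1e-12)
        assert fc.values[2, 2, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_scalar_correlation_oracle(self, rng):
        shape = (3, 3, 2)
        mask = np.ones(shape, dtype=bool)
        seed = rng.standard_normal(25)
        data = rng.standard_normal(shape + (25,))
        fc = fc_map_subject(seed, data, mask)
        for idx in [(0, 0, 0), (1, 2, 1), (2, 2, 1)]:
            assert fc.values[idx] == pytest.approx(np.corrcoef(seed, data[idx])[0, 1],
                                                   abs=1e-12)

    def test_zero_variance_voxel_warns_and_gets_zero(self, rng):
        shape = (3, 3, 2)
        mask = np.ones(shape, dtype=bool)
        data = rng.standard_normal(shape + (25,))
        data[0, 0, 0] = 3.0
        with pytest.warns(UserWarning):
            fc = fc_map_subject(rng.standard_normal(25), data, mask)
        assert fc.values[0, 0, 0] == 0.0


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_matches_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), rel=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.54931, abs=1e-5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-0.999, max_value=0.999))
    def test_odd_function_and_round_trip(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)
        assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_saturated_r_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            z = fisher_z(1.0)
        assert np.isfinite(z)


class TestGroupFcMaps:
    def test_degenerate_zero_variance_voxels_masked(self, rng):
        shape = (4, 4, 3)
        mask = np.ones(shape, dtype=bool)
        shared = rng.standard_normal(shape)
        z_maps = [shared.copy() for _ in range(6)]
        groups = ["A"] * 3 + ["B"] * 3
        with pytest.warns(UserWarning):
            maps = group_fc_maps(z_maps, groups, mask)
        assert not maps["one_sample_A"].mask.any()

    def test_label_swap_negates_between_map(self, rng):
        shape = (4, 4, 3)
        mask = np.ones(shape, dtype=bool)
        z_maps = [rng.standard_normal(shape) for _ in range(7)]
        groups = ["A"] * 3 + ["B"] * 4
        swapped = ["B" if g == "A" else "A" for g in groups]
        m1 = group_fc_maps(z_maps, groups, mask)["between"]
        m2 = group_fc_maps(z_maps, swapped, mask)["between"]
        np.testing.assert_allclose(m2.t_values, -m1.t_values, atol=1e-10)

    def test_one_sample_maps_have_per_group_df(self, rng):
        shape = (4, 4, 3)
        mask = np.ones(shape, dtype=bool)
        z_maps = [rng.standard_normal(shape) for _ in range(9)]
        groups = ["A"] * 4 + ["B"] * 5
        maps = group_fc_maps(z_maps, groups, mask)
        assert maps["one_sample_A"].df == 3
        assert maps["one_sample_B"].df == 4
        assert maps["between"].df == 7

    def test_z_space_conversion(self, rng):
        shape = (3, 3, 2)
        mask = np.ones(shape, dtype=bool)
        seed = rng.standard_normal(30)
        data = rng.standard_normal(shape + (30,))
        fc = fc_map_subject(seed, data, mask)
        z = fc_z_map(fc)
        np.testing.assert_allclose(z.values[mask], np.arctanh(fc.values[mask]),
                                   atol=1e-12)
        assert z.space == "z"
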