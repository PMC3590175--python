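import numpy as np
import pytest
from scipy import stats

from restalff.coords import make_affine
from restalff.group_stats import (
    StatMap,
    alphasim_min_extent,
    bonferroni_t_threshold,
    cluster_report,
    label_clusters,
    t_critical,
    two_sample_t_map,
)


class TestTCritical:
    def test_reference_threshold_alpha_001_df_28(self):
        # the classic |T| > 2.7633 voxel threshold at p < 0.01, df = 28
        assert t_critical(0.01, 28) == pytest.approx(2.7633, abs=5e-4)

    def test_large_df_approaches_normal_quantile(self):
        assert t_critical(0.05, 10**7) == pytest.approx(1.95996, abs=1e-4)

    def test_alpha_one_gives_zero(self):
        assert t_critical(1.0, 10) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_critical(0.0, 10)
        with pytest.raises(ValueError):
            t_critical(0.05, 0)

    def test_statmap_threshold_consistent_with_quantile_oracle(self):
        sm = StatMap(t_values=np.zeros((2, 2, 2)), df=30, mask=np.ones((2, 2, 2), bool),
                     voxel_p_threshold=0.01)
        q = sm.t_critical
        # numeric oracle: two-tailed tail mass at q equals alpha
        assert 2 * stats.t.sf(q, 30) == pytest.approx(0.01, rel=1e-9)

    def test_bonferroni_threshold(self):
        assert bonferroni_t_threshold(0.05, 30, 1000) == pytest.approx(
            t_critical(0.05 / 1000, 30)
        )


class TestTwoSampleTMap:
    def _groups(self, rng, shape=(5, 5, 4), n_a=6, n_b=7):
        a = [rng.standard_normal(shape) for _ in range(n_a)]
        b = [rng.standard_normal(shape) for _ in range(n_b)]
        return a, b, np.ones(shape, dtype=bool)

    def test_identical_groups_give_zero(self, rng):
        a, _, mask = self._groups(rng)
        stat = two_sample_t_map(a, a, mask)
        np.testing.assert_allclose(stat.t_values, 0.0, atol=1e-12)
        assert stat.df == 10

    def test_matches_scalar_statistics_oracle(self, rng):
        a, b, mask = self._groups(rng)
        stat = two_sample_t_map(a, b, mask)
        A, B = np.stack(a, -1), np.stack(b, -1)
        for idx in [(0, 0, 0), (2, 3, 1), (4, 4, 3)]:
            expected = stats.ttest_ind(B[idx], A[idx], equal_var=True).statistic
            assert stat.t_values[idx] == pytest.approx(expected, rel=1e-10)

    def test_label_swap_negates_map(self, rng):
        a, b, mask = self._groups(rng)
        s1 = two_sample_t_map(a, b, mask)
        s2 = two_sample_t_map(b, a, mask)
        np.testing.assert_allclose(s2.t_values, -s1.t_values, atol=1e-10)

    def test_zero_variance_voxel_warns_and_zeroes(self, rng):
        a, b, mask = self._groups(rng)
        for m in a + b:
            m[0, 0, 0] = 5.0
        with pytest.warns(UserWarning):
            stat = two_sample_t_map(a, b, mask)
        assert stat.t_values[0, 0, 0] == 0.0

    def test_single_subject_group_rejected(self, rng):
        a, b, mask = self._groups(rng, n_a=1)
        with pytest.raises(ValueError):
            two_sample_t_map(a, b, mask)


def _flood_fill_components(binary, connectivity):
    """Brute-force flood-fill oracle for connected-component counting."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and order == 1) or (
                    connectivity == 18 and order <= 2
                ) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    seen = np.zeros_like(binary, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[i] < binary.shape[i] for i in range(3)):
                    if binary[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
        components.append(sorted(comp))
    return components


class TestLabelClusters:
    def test_face_touching_voxels_one_cluster_everywhere(self):
        vol = np.zeros((4, 4, 4), dtype=bool)
        vol[1, 1, 1] = vol[1, 1, 2] = True
        for conn in (6, 18, 26):
            assert len(label_clusters(vol, conn)) == 1

    def test_corner_touching_voxels_split_under_6_and_18(self):
        vol = np.zeros((4, 4, 4), dtype=bool)
        vol[1, 1, 1] = vol[2, 2, 2] = True
        assert len(label_clusters(vol, 6)) == 2
        assert len(label_clusters(vol, 18)) == 2
        assert len(label_clusters(vol, 26)) == 1

    def test_edge_touching_voxels_join_under_18(self):
        vol = np.zeros((4, 4, 4), dtype=bool)
        vol[1, 1, 1] = vol[2, 2, 1] = True
        assert len(label_clusters(vol, 6)) == 2
        assert len(label_clusters(vol, 18)) == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_maps(self, connectivity):
        rng = np.random.default_rng(99)
        for _ in range(5):
            vol = rng.random((8, 8, 8)) < 0.25
            ours = label_clusters(vol, connectivity)
            oracle = _flood_fill_components(vol, connectivity)
            assert len(ours) == len(oracle)
            assert sorted(len(c) for c in ours) == sorted(len(c) for c in oracle)

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            label_clusters(np.zeros((3, 3, 3), bool), 10)

    def test_deterministic_ordering_by_size_then_coordinate(self):
        vol = np.zeros((6, 6, 6), dtype=bool)
        vol[4, 4, 4] = True  # size 1
        vol[0, 0, 0] = vol[0, 0, 1] = True  # size 2
        vol[2, 2, 2] = True  # size 1, lexicographically before (4,4,4)
        clusters = label_clusters(vol, 6)
        assert len(clusters[0]) == 2
        assert tuple(clusters[1][0]) == (2, 2, 2)
        assert tuple(clusters[2][0]) == (4, 4, 4)


class TestAlphaSim:
    def test_unsmoothed_suprathreshold_count_matches_binomial(self):
        # independent voxels: expected suprathreshold fraction is exactly
        # the two-tailed voxel p; 4000 voxels at p=0.01 -> 40 per iteration
        mask = np.ones((20, 20, 10), dtype=bool)  # 4000 voxels
        rng = np.random.default_rng(5)
        z = stats.norm.ppf(1 - 0.01 / 2)
        counts = []
        for _ in range(2000):
            vals = rng.standard_normal(4000)
            vals = (vals - vals.mean()) / vals.std()
            counts.append((np.abs(vals) > z).sum())
        assert np.mean(counts) == pytest.approx(40.0, abs=3.0)

    def test_k_min_monotone_in_voxel_p(self):
        mask = np.ones((16, 16, 10), dtype=bool)
        shared = dict(fwhm_mm=8.0, voxel_size_mm=3.0, n_iter=1000, connectivity=6)
        strict = alphasim_min_extent(mask, voxel_p=0.001,
                                     rng=np.random.default_rng(7), **shared)
        loose = alphasim_min_extent(mask, voxel_p=0.01,
                                    rng=np.random.default_rng(7), **shared)
        assert strict.k_min <= loose.k_min

    def test_corrected_alpha_one_gives_k_min_one(self):
        mask = np.ones((10, 10, 8), dtype=bool)
        res = alphasim_min_extent(mask, 0.0, 3.0, corrected_alpha=1.0, n_iter=1000,
                                  rng=np.random.default_rng(3))
        assert res.k_min == 1

    def test_deterministic_under_fixed_seed(self):
        mask = np.ones((12, 12, 8), dtype=bool)
        r1 = alphasim_min_extent(mask, 8.0, 3.0, n_iter=1000,
                                 rng=np.random.default_rng(42))
        r2 = alphasim_min_extent(mask, 8.0, 3.0, n_iter=1000,
                                 rng=np.random.default_rng(42))
        assert r1.k_min == r2.k_min
        np.testing.assert_array_equal(r1.null_max_sizes, r2.null_max_sizes)

    def test_invalid_probabilities_rejected(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        with pytest.raises(ValueError):
            alphasim_min_extent(mask, 8.0, 3.0, voxel_p=0.0)
        with pytest.raises(ValueError):
            alphasim_min_extent(mask, 8.0, 3.0, corrected_alpha=1.5)

    def test_tail_probability_at_k_min_controls_alpha(self):
        mask = np.ones((14, 14, 10), dtype=bool)
        res = alphasim_min_extent(mask, 8.0, 3.0, n_iter=1000,
                                  rng=np.random.default_rng(11))
        assert res.tail_probability(res.k_min) <= 0.05
        assert res.tail_probability(res.k_min - 1) > 0.05


class TestClusterReport:
    def _stat(self, t_values, mask=None):
        t_values = np.asarray(t_values, dtype=float)
        if mask is None:
            mask = np.ones(t_values.shape, dtype=bool)
        return StatMap(t_values=t_values, df=30, mask=mask, voxel_p_threshold=0.01)

    def test_small_cluster_below_extent_dropped(self):
        t = np.zeros((10, 10, 10))
        t[2:4, 2:4, 2:4] = 5.0  # 8 voxels, then extend to 10
        t[4, 2, 2] = t[4, 2, 3] = 5.0
        affine = make_affine((10, 10, 10), 3.0)
        report = cluster_report(self._stat(t), k_min=16, affine=affine)
        assert len(report) == 0

    def test_surviving_cluster_reported_with_peak(self):
        t = np.zeros((10, 10, 10))
        t[2:5, 2:5, 2:4] = 4.0  # 18 voxels
        t[3, 3, 2] = 6.5
        affine = make_affine((10, 10, 10), 3.0)
        report = cluster_report(self._stat(t), k_min=16, affine=affine)
        assert len(report) == 1
        row = report.iloc[0]
        assert row.cluster_size == 18 and row.sign == 1
        assert row.peak_t == pytest.approx(6.5)
        expected = affine[:3, :3] @ [3, 3, 2] + affine[:3, 3]
        assert (row.x_mm, row.y_mm, row.z_mm) == tuple(expected)

    def test_negative_clusters_carry_sign(self):
        t = np.zeros((10, 10, 10))
        t[5:8, 5:8, 5:7] = -4.0
        affine = make_affine((10, 10, 10), 3.0)
        report = cluster_report(self._stat(t), k_min=10, affine=affine)
        assert len(report) == 1 and report.iloc[0].sign == -1

    def test_peak_tie_breaks_lexicographically(self):
        t = np.zeros((8, 8, 8))
        t[1:3, 1:3, 1:3] = 4.0  # all equal: peak must be (1,1,1)
        affine = make_affine((8, 8, 8), 3.0)
        report = cluster_report(self._stat(t), k_min=1, affine=affine)
        expected = affine[:3, :3] @ [1, 1, 1] + affine[:3, 3]
        assert (report.iloc[0].x_mm, report.iloc[0].y_mm, report.iloc[0].z_mm) == tuple(expected)

    def test_excluded_voxels_removed_before_clustering(self):
        t = np.zeros((8, 8, 8))
        t[1:4, 1:4, 1:3] = 5.0
        affine = make_affine((8, 8, 8), 3.0)
        excl = np.argwhere(t > 0)
        report = cluster_report(self._stat(t), k_min=1, affine=affine,
                                exclude_voxels=excl)
        assert len(report) == 0
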