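import numpy as np
import pytest
from scipy import stats

from slpattern import (
    InferenceConfig,
    VolumeGrid,
    accuracy_to_pmap,
    binomial_tail_p,
    label_clusters,
    permutation_test_cluster,
)
from slpattern.cluster_inference import PMap, run_cluster_permutations
from slpattern.searchlight_mvpa import AccuracyMap


class TestBinomialTail:
    def test_whole_sample_space(self):
        assert binomial_tail_p(0, 29) == 1.0

    def test_single_outcome(self):
        assert binomial_tail_p(29, 29) == 2.0**-29

    def test_k23_n29_exact(self):
        # frozen from exact rational arithmetic: sum_{j=23..29} C(29,j) / 2^29
        assert binomial_tail_p(23, 29) == pytest.approx(0.0011578500270843506, rel=0, abs=1e-18)

    def test_matches_scipy_oracle_up_to_n64(self):
        for n in range(1, 65):
            ks = np.arange(0, n + 1)
            ours = np.array([binomial_tail_p(k, n) for k in ks])
            oracle = stats.binom.sf(ks - 1, n, 0.5)
            np.testing.assert_allclose(ours, oracle, rtol=1e-12)

    def test_strictly_decreasing_in_k(self):
        import math
        from fractions import Fraction

        for n in (5, 29, 64):
            ps = [binomial_tail_p(k, n) for k in range(n + 1)]
            assert all(b <= a for a, b in zip(ps, ps[1:]))
            # strictness holds in exact arithmetic (float collapses
            # 1 - 2^-64 to 1.0, so check the rational tail directly)
            exact = [
                Fraction(sum(math.comb(n, j) for j in range(k, n + 1)), 2**n)
                for k in range(n + 1)
            ]
            assert all(b < a for a, b in zip(exact, exact[1:]))

    def test_strict_tail_variant(self):
        assert binomial_tail_p(10, 29, strict=True) == binomial_tail_p(11, 29)

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_arguments(self, k, n):
        with pytest.raises(ValueError):
            binomial_tail_p(k, n)


def _acc_map(values, n_subjects, grid=None):
    values = np.asarray(values, dtype=float)
    grid = grid or VolumeGrid(values.shape, 1.5)
    return AccuracyMap(grid=grid, accuracy=values, n_subjects=n_subjects)


class TestAccuracyToPmap:
    def test_perfect_accuracy(self):
        amap = _acc_map(np.ones((4, 4, 4)), 29)
        assert (accuracy_to_pmap(amap).p == 2.0**-29).all()

    def test_zero_accuracy(self):
        amap = _acc_map(np.zeros((4, 4, 4)), 29)
        assert (accuracy_to_pmap(amap).p == 1.0).all()

    def test_constant_map_pointwise(self):
        amap = _acc_map(np.full((3, 3, 3), 20 / 29), 29)
        pm = accuracy_to_pmap(amap)
        assert np.unique(pm.p).size == 1
        assert pm.p[0, 0, 0] == binomial_tail_p(20, 29)

    def test_nan_outside_mask_preserved(self):
        vals = np.full((4, 4, 4), np.nan)
        vals[2, 2, 2] = 1.0
        amap = _acc_map(vals, 10)
        pm = accuracy_to_pmap(amap)
        assert np.isnan(pm.p[0, 0, 0]) and pm.p[2, 2, 2] == 2.0**-10

    def test_out_of_range_rejected(self):
        amap = _acc_map(np.full((3, 3, 3), 1.5), 10)
        with pytest.raises(ValueError):
            accuracy_to_pmap(amap)


def _pmap_from_mask(supra, n=29):
    """p-map with p=1e-6 on `supra` voxels, 0.5 elsewhere."""
    p = np.where(supra, 1e-6, 0.5)
    grid = VolumeGrid(supra.shape, 1.5)
    return PMap(grid=grid, p=p, n_subjects=n)


class TestLabelClusters:
    def test_cube_counts_as_one_cluster(self):
        supra = np.zeros((12, 12, 12), bool)
        supra[4:8, 4:8, 4:8] = True
        cs = label_clusters(_pmap_from_mask(supra), InferenceConfig(min_size=50))
        assert len(cs) == 1
        assert cs.clusters[0].size == 64

    def test_corner_touch_split_under_18_joined_under_26(self):
        supra = np.zeros((10, 10, 10), bool)
        supra[2:4, 2:4, 2:4] = True
        supra[4:6, 4:6, 4:6] = True  # touches only through the (3,3,3)-(4,4,4) corner
        cs18 = label_clusters(
            _pmap_from_mask(supra), InferenceConfig(min_size=1, connectivity=18)
        )
        cs26 = label_clusters(
            _pmap_from_mask(supra), InferenceConfig(min_size=1, connectivity=26)
        )
        assert len(cs18) == 2
        assert len(cs26) == 1

    def test_edge_touch_joined_under_18_split_under_6(self):
        supra = np.zeros((10, 10, 10), bool)
        supra[2, 2, 2] = True
        supra[3, 3, 2] = True  # shares an edge
        cs18 = label_clusters(
            _pmap_from_mask(supra), InferenceConfig(min_size=1, connectivity=18)
        )
        cs6 = label_clusters(
            _pmap_from_mask(supra), InferenceConfig(min_size=1, connectivity=6)
        )
        assert len(cs18) == 1
        assert len(cs6) == 2

    def test_49_voxels_filtered_at_min_size_50(self):
        supra = np.zeros((12, 12, 12), bool)
        supra[4:8, 4:8, 4:7] = True  # 4*4*3 = 48
        supra[4, 4, 7] = True  # 49th voxel
        cs = label_clusters(_pmap_from_mask(supra), InferenceConfig(min_size=50))
        assert len(cs) == 0

    def test_exactly_50_survives(self):
        supra = np.zeros((12, 12, 12), bool)
        supra[4:8, 4:8, 4:7] = True
        supra[4, 4, 7] = True
        supra[4, 5, 7] = True  # 50
        cs = label_clusters(_pmap_from_mask(supra), InferenceConfig(min_size=50))
        assert len(cs) == 1 and cs.clusters[0].size == 50

    def test_ordered_by_size_descending(self):
        supra = np.zeros((20, 20, 20), bool)
        supra[1:3, 1:3, 1:3] = True  # 8
        supra[10:14, 10:14, 10:14] = True  # 64
        cs = label_clusters(_pmap_from_mask(supra), InferenceConfig(min_size=1))
        assert [c.size for c in cs.clusters] == [64, 8]

    def test_peak_is_minimal_p_with_lexicographic_ties(self):
        supra = np.zeros((8, 8, 8), bool)
        supra[2:5, 2, 2] = True
        p = np.where(supra, 1e-6, 0.5)
        p[3, 2, 2] = 1e-9
        pm = PMap(grid=VolumeGrid((8, 8, 8), 1.5), p=p, n_subjects=20)
        cs = label_clusters(pm, InferenceConfig(min_size=1))
        assert cs.clusters[0].peak == (3, 2, 2)
        # all-tied case: first voxel in lexicographic order
        cs2 = label_clusters(_pmap_from_mask(supra), InferenceConfig(min_size=1))
        assert cs2.clusters[0].peak == (2, 2, 2)

    def test_label_volume_partitions_suprathreshold(self):
        supra = np.zeros((10, 10, 10), bool)
        supra[2:6, 2:6, 2:6] = True
        cs = label_clusters(_pmap_from_mask(supra), InferenceConfig(min_size=1))
        assert (cs.labels > 0).sum() == supra.sum()

    def test_peak_accuracy_reported(self):
        supra = np.zeros((8, 8, 8), bool)
        supra[3:5, 3:5, 3:5] = True
        amap = _acc_map(np.where(supra, 0.9, 0.5), 29)
        pm = accuracy_to_pmap(amap)
        cs = label_clusters(pm, InferenceConfig(voxel_alpha=1e-3, min_size=1), accuracy=amap)
        assert cs.clusters[0].peak_accuracy == pytest.approx(0.9)


class TestPermutationTest:
    def test_separable_reaches_smallest_achievable_p(self, rng):
        X = np.vstack([
            rng.normal(0, 0.05, size=(7, 10)),
            rng.normal(5, 0.05, size=(8, 10)),
        ])
        y = np.array([0] * 7 + [1] * 8)
        p, observed = permutation_test_cluster(X, y, n_perm=200, seed=3)
        assert observed == 1.0
        assert p == pytest.approx(1 / 201)

    def test_add_one_never_zero(self, rng):
        X = rng.normal(size=(12, 5))
        y = np.array([0] * 6 + [1] * 6)
        p, _ = permutation_test_cluster(X, y, n_perm=19, seed=0)
        assert p >= 1 / 20

    def test_seeded_reproducibility(self, rng):
        X = rng.normal(size=(12, 5))
        y = np.array([0] * 6 + [1] * 6)
        p1, _ = permutation_test_cluster(X, y, n_perm=50, seed=9)
        p2, _ = permutation_test_cluster(X, y, n_perm=50, seed=9)
        assert p1 == p2

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_test_cluster(
                rng.normal(size=(8, 3)), np.array([0] * 4 + [1] * 4), n_perm=0
            )

    def test_run_cluster_permutations_attaches_p(self, blob_cohort):
        cohort, _ = blob_cohort
        from slpattern import searchlight_map

        amap = searchlight_map(cohort.volumes, cohort.labels(), cohort.grid, 5.0)
        pm = accuracy_to_pmap(amap)
        cfg = InferenceConfig(voxel_alpha=0.05, min_size=5, n_permutations=30, seed=4)
        cs = label_clusters(pm, cfg, accuracy=amap)
        assert len(cs) >= 1
        run_cluster_permutations(cohort.volumes, cohort.labels(), cs, cfg=cfg)
        for c in cs.clusters:
            assert c.perm_p is not None and 0 < c.perm_p <= 1


def test_inference_config_validation():
    with pytest.raises(ValueError):
        InferenceConfig(voxel_alpha=0.0)
    with pytest.raises(ValueError):
        InferenceConfig(min_size=0)
    with pytest.raises(ValueError):
        InferenceConfig(connectivity=10)
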