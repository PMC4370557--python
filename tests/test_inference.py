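"""Permutation machinery, empirical p-values, FDR and cluster filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rewardlight.inference import (
    PermutationConfig,
    build_null_svc,
    cluster_filter,
    empirical_pvalue,
    fdr_bh,
    generate_label_permutations,
)
from rewardlight.svm import SolverConfig
from rewardlight.volumes import MaskVolume, SearchlightSpec, StatMap, SubjectVolumeStack, VoxelGrid


class TestLabelPermutations:
    def test_tiny_cohort_draws_from_nonidentity_arrangements(self):
        labels = np.array([1, 1, -1, -1])
        perms = generate_label_permutations(labels, 5, seed=0)
        assert perms.shape == (5, 4)
        for p in perms:
            assert sorted(p) == [-1, -1, 1, 1]
            assert not np.array_equal(p, labels)

    def test_request_beyond_distinct_arrangements_rejected(self):
        labels = np.array([1, 1, -1, -1])  # C(4,2)-1 = 5 non-identity arrangements
        with pytest.raises(ValueError, match="distinct"):
            generate_label_permutations(labels, 6, seed=0)

    def test_deterministic_given_seed(self):
        labels = np.concatenate([np.ones(10), -np.ones(10)])
        a = generate_label_permutations(labels, 20, seed=5)
        b = generate_label_permutations(labels, 20, seed=5)
        assert np.array_equal(a, b)

    def test_class_counts_preserved(self):
        labels = np.concatenate([np.ones(44), -np.ones(44)])
        perms = generate_label_permutations(labels, 25, seed=1)
        assert ((perms == 1).sum(axis=1) == 44).all()
        assert ((perms == -1).sum(axis=1) == 44).all()


class TestEmpiricalPvalue:
    def test_observed_above_all_nulls(self):
        assert empirical_pvalue(99.5, np.arange(99)) == pytest.approx(1 / 100)

    def test_observed_at_null_minimum(self):
        null = np.arange(99, dtype=float)
        assert empirical_pvalue(0.0, null) == pytest.approx(1.0)

    def test_four_of_99_at_or_above(self):
        null = np.concatenate([np.zeros(95), np.full(4, 7.0)])
        assert empirical_pvalue(5.0, null) == pytest.approx(0.05)

    def test_vectorised_form_matches_scalar(self, rng):
        null = rng.standard_normal((199, 7))
        obs = rng.standard_normal(7)
        vec = empirical_pvalue(obs, null)
        for j in range(7):
            assert vec[j] == pytest.approx(empirical_pvalue(obs[j], null[:, j]))

    def test_min_attainable_p_is_one_over_nperm_plus_one(self, rng):
        null = rng.standard_normal(199)
        assert empirical_pvalue(1e9, null) == pytest.approx(1 / 200)

    def test_nonfinite_observed_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(np.nan, np.arange(10))


def brute_force_bh(p, q):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            kmax = rank
    reject[order[:kmax]] = True
    return reject


class TestFdrBh:
    def test_all_small_p_rejected(self):
        reject, thr = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.05], 0.05)
        assert reject.all() and thr == pytest.approx(0.05)

    def test_single_marginal_p_not_rejected(self):
        reject, thr = fdr_bh([0.04, 0.9, 0.9, 0.9], 0.05)
        assert not reject.any() and thr == 0.0

    def test_all_ones_rejected_none(self):
        reject, _ = fdr_bh(np.ones(10), 0.05)
        assert not reject.any()

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_stepup(self, seed):
        r = np.random.default_rng(seed)
        m = int(r.integers(1, 40))
        p = np.round(r.random(m), 3)
        q = float(r.choice([0.01, 0.05, 0.1, 0.2]))
        reject, _ = fdr_bh(p, q)
        assert np.array_equal(reject, brute_force_bh(p, q))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(2, 200))
            reject, _ = fdr_bh(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(reject, ref)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([], 0.05)


class TestClusterFilter:
    @staticmethod
    def _grid_map(shape=(12, 12, 10)):
        return np.zeros(shape, dtype=int)

    def test_blob_below_extent_threshold_removed(self):
        m = self._grid_map()
        m[1:4, 1:4, 1:4] = 1  # 27 voxels
        m[1, 1, 4] = 1
        m[1, 2, 4] = 1  # total 29
        table, filtered = cluster_filter(m, min_size=30, connectivity=6)
        assert len(table) == 0 and not filtered.any()

    def test_blob_at_exact_threshold_retained(self):
        m = self._grid_map()
        m[1:4, 1:4, 1:4] = 1
        m[1, 1, 4] = 1
        m[1, 2, 4] = 1
        m[1, 3, 4] = 1  # total 30
        table, filtered = cluster_filter(m, min_size=30, connectivity=6)
        assert len(table) == 1
        assert table.iloc[0]["size_voxels"] == 30
        assert filtered.sum() == 30

    def test_corner_touching_blobs_merge_only_under_26_connectivity(self):
        m = self._grid_map()
        m[1:6, 1:5, 1] = 1  # 20 voxels
        m[6:9, 5:10, 2] = 1  # 15 voxels, touches only at a corner
        t6, f6 = cluster_filter(m, min_size=30, connectivity=6)
        assert len(t6) == 0
        t26, f26 = cluster_filter(m, min_size=30, connectivity=26)
        assert len(t26) == 1
        assert t26.iloc[0]["size_voxels"] == 35

    def test_peak_reported_from_companion_stat_map(self):
        grid = VoxelGrid((12, 12, 10))
        m = self._grid_map()
        m[2:6, 2:6, 2:5] = 1
        stat = np.zeros(grid.dims)
        stat[4, 5, 3] = 99.0
        table, _ = cluster_filter(m, min_size=10, connectivity=18,
                                  stat_map=StatMap(grid, stat, "acc"))
        row = table.iloc[0]
        assert (row["peak_i"], row["peak_j"], row["peak_k"]) == (4, 5, 3)
        assert row["peak_stat"] == 99.0
        assert (row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"]) == (12.0, 15.0, 9.0)

    def test_non_binary_input_rejected(self):
        m = self._grid_map()
        m[0, 0, 0] = 3
        with pytest.raises(ValueError, match="binary"):
            cluster_filter(m)


class TestNullSvc:
    @staticmethod
    def _small_problem(rng, seed=0):
        grid = VoxelGrid((6, 6, 4))
        n = 12
        labels = np.concatenate([np.ones(6), -np.ones(6)])
        stack = SubjectVolumeStack(
            grid, [f"s{i}" for i in range(n)], rng.standard_normal((n, *grid.dims))
        )
        m = np.zeros(grid.dims, dtype=bool)
        m[2:4, 2:4, 1:3] = True
        mask = MaskVolume(grid, m, "box")
        return stack, labels, mask

    def test_same_seed_identical_null(self, rng):
        stack, labels, mask = self._small_problem(rng)
        kw = dict(spec=SearchlightSpec(2), solver=SolverConfig(max_iter=200))
        pc = PermutationConfig(n_perm=10, seed=4)
        a = build_null_svc(stack, labels, mask, perm_config=pc, **kw)
        b = build_null_svc(stack, labels, mask, perm_config=pc, **kw)
        assert np.array_equal(a.samples, b.samples)

    def test_single_permutation_null_accepted(self, rng):
        stack, labels, mask = self._small_problem(rng)
        null = build_null_svc(
            stack, labels, mask, SearchlightSpec(2), SolverConfig(max_iter=200),
            PermutationConfig(n_perm=1, seed=0),
        )
        assert null.samples.shape[0] == 1

    def test_summary_reports_voxelwise_min_mean_max(self, rng):
        stack, labels, mask = self._small_problem(rng)
        null = build_null_svc(
            stack, labels, mask, SearchlightSpec(2), SolverConfig(max_iter=200),
            PermutationConfig(n_perm=25, seed=2),
        )
        s = null.summary()
        mmm = null.voxel_min_mean_max()
        assert s["mean_min"] == pytest.approx(mmm[:, 0].mean())
        assert s["mean_min"] <= s["mean_mean"] <= s["mean_max"]
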