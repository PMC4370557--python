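"""Synthetic cohort generator: masks, determinism, planted effects, noise shape."""

import numpy as np
import pytest
from scipy import stats

from rewardlight.searchlight import run_searchlight_svc
from rewardlight.svm import SolverConfig
from rewardlight.synthetic import (
    RoiSpec,
    SyntheticConfig,
    fleishman_coefficients,
    generate_cohort,
    generate_roi_mask,
    generate_symptom_scores,
    shaped_noise,
    variance_asymmetry_experiment,
    write_cohort,
)
from rewardlight.univariate import two_sample_t
from rewardlight.volumes import MaskVolume, SearchlightSpec, VoxelGrid, read_cohort_table


class TestRoiMask:
    def test_radius_two_sphere_has_33_voxels(self):
        grid = VoxelGrid((20, 20, 20))
        m = generate_roi_mask(RoiSpec((10, 10, 10), 2.0, "r2"), grid)
        assert m.n_voxels == 33

    def test_radius_zero_is_single_voxel(self):
        grid = VoxelGrid((9, 9, 9))
        m = generate_roi_mask(RoiSpec((4, 4, 4), 0.0, "pt"), grid)
        assert m.n_voxels == 1

    def test_disjoint_specs_give_disjoint_masks(self):
        grid = VoxelGrid((24, 16, 12))
        a = generate_roi_mask(RoiSpec((5, 8, 6), 2.0, "a"), grid)
        b = generate_roi_mask(RoiSpec((18, 8, 6), 2.0, "b"), grid)
        assert not (a.data & b.data).any()

    def test_out_of_bounds_sphere_names_the_spec(self):
        grid = VoxelGrid((10, 10, 10))
        with pytest.raises(ValueError, match="'too_big'"):
            generate_roi_mask(RoiSpec((1, 5, 5), 3.0, "too_big"), grid)


class TestCohortGeneration:
    def test_identical_config_is_bit_reproducible(self):
        cfg = SyntheticConfig(grid_dims=(10, 10, 8), n_per_group=6,
            roi_specs=(RoiSpec((5, 5, 4), 2.0, "roi"),), seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert np.array_equal(a.stack.data, b.stack.data)
        assert a.table.equals(b.table)
        for k in a.ground_truth.pattern_vectors:
            assert np.array_equal(
                a.ground_truth.pattern_vectors[k], b.ground_truth.pattern_vectors[k]
            )

    def test_group_sizes_and_label_coding(self):
        cfg = SyntheticConfig(grid_dims=(10, 10, 8), n_per_group=9,
            roi_specs=(RoiSpec((5, 5, 4), 2.0, "roi"),), seed=0)
        c = generate_cohort(cfg)
        assert (c.labels == 1).sum() == 9 and (c.labels == -1).sum() == 9
        assert (c.table["group"] == "patient").sum() == 9

    def test_pattern_vector_zero_mean_over_roi(self):
        cfg = SyntheticConfig(grid_dims=(14, 14, 10), n_per_group=4, seed=1)
        c = generate_cohort(cfg)
        for pat in c.ground_truth.pattern_vectors.values():
            assert abs(pat.mean()) < 1e-12

    def test_pure_null_roi_mean_t_is_calibrated(self):
        # no planted effects: the two group mean volumes differ only by noise
        hits = 0
        for seed in range(25):
            cfg = SyntheticConfig(
                grid_dims=(8, 8, 6), n_per_group=10, univariate_shift=0.0,
                pattern_amplitude=0.0, smoothing_fwhm=0.0,
                roi_specs=(RoiSpec((4, 4, 3), 2.0, "roi"),),
                noise_sd_control=1.0, noise_sd_patient=1.0, seed=seed,
            )
            c = generate_cohort(cfg)
            roi = c.ground_truth.roi_voxel_indices["roi"]
            vals = c.stack.data[:, roi[:, 0], roi[:, 1], roi[:, 2]].mean(axis=1)
            _, _, p = two_sample_t(vals[c.labels == -1], vals[c.labels == 1])
            hits += p < 0.05
        assert hits <= 5  # ~binomial(25, 0.05)

    def test_pure_pattern_is_decodable_but_mean_silent(self):
        # the multivariate-beats-univariate regime: ROI-mean t ~ 0 while
        # searchlight accuracy in the ROI is far above chance
        cfg = SyntheticConfig(
            grid_dims=(12, 12, 10), n_per_group=20, univariate_shift=0.0,
            pattern_amplitude=2.0, expression_sd=0.5,
            roi_specs=(RoiSpec((6, 6, 5), 2.83, "roi"),), seed=4,
        )
        c = generate_cohort(cfg)
        roi = c.ground_truth.roi_voxel_indices["roi"]
        vals = c.stack.data[:, roi[:, 0], roi[:, 1], roi[:, 2]].mean(axis=1)
        t, _, _ = two_sample_t(vals[c.labels == -1], vals[c.labels == 1])
        assert abs(t) < 2.5
        mask = generate_roi_mask(cfg.roi_specs[0], cfg.grid())
        dec = run_searchlight_svc(
            c.stack, c.labels, mask, SearchlightSpec(6), SolverConfig(max_iter=300), 4
        )
        assert np.nanmax(dec.accuracy.data) > 75.0

    def test_invalid_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd_control=0.0)


class TestSymptomScores:
    def test_noise_free_scores_track_expression_perfectly(self):
        cfg = SyntheticConfig(
            grid_dims=(10, 10, 8), n_per_group=10, roi_specs=(),
            symptom_noise_sd=0.0, seed=2
        )
        c = generate_cohort(cfg)
        scores = generate_symptom_scores(c, cfg)
        expr = c.ground_truth.expression[c.patient_mask]
        assert stats.spearmanr(scores, expr).statistic == pytest.approx(1.0)

    def test_zero_slope_decouples_scores(self):
        rhos = []
        for seed in range(15):
            cfg = SyntheticConfig(
                grid_dims=(8, 8, 6), n_per_group=44, roi_specs=(),
                symptom_slope=0.0, seed=seed
            )
            c = generate_cohort(cfg)
            scores = generate_symptom_scores(c, cfg)
            expr = c.ground_truth.expression[c.patient_mask]
            rhos.append(stats.spearmanr(scores, expr).statistic)
        assert abs(np.mean(rhos)) < 0.1

    def test_default_coupling_gives_population_spearman_near_07(self, rng):
        # slope 3, noise 3, unit expression SD -> Pearson 0.707, Spearman ~0.69
        expr = rng.standard_normal(200_000)
        score = 3.0 * expr + 3.0 * rng.standard_normal(expr.size)
        rho = stats.spearmanr(expr, score).statistic
        assert rho == pytest.approx(0.69, abs=0.02)

    def test_requires_patients(self):
        cfg = SyntheticConfig(grid_dims=(8, 8, 6), n_per_group=4, roi_specs=(), seed=0)
        c = generate_cohort(cfg)
        c.labels = -np.ones_like(c.labels)  # simulate a patient-free cohort
        with pytest.raises(ValueError, match="no patients"):
            generate_symptom_scores(c, cfg)


class TestNoiseShaping:
    @pytest.mark.parametrize("skew,kurt", [(0.75, 0.0), (0.0, 2.0), (-0.5, 1.0)])
    def test_power_method_moments_within_5pct(self, skew, kurt, rng):
        x = shaped_noise(rng, 400_000, sd=1.0, skewness=skew, kurtosis_excess=kurt)
        assert np.std(x) == pytest.approx(1.0, rel=0.05)
        if skew != 0:
            assert stats.skew(x) == pytest.approx(skew, rel=0.05, abs=0.02)
        if kurt != 0:
            assert stats.kurtosis(x) == pytest.approx(kurt, rel=0.1)

    def test_gaussian_passthrough(self):
        assert fleishman_coefficients(0.0, 0.0) == (0.0, 1.0, 0.0, 0.0)

    def test_infeasible_shape_rejected(self):
        # excess kurtosis far below the attainable boundary for the skewness
        with pytest.raises(ValueError, match="transform"):
            fleishman_coefficients(2.0, -2.0)


class TestVarianceAsymmetryExperiment:
    BASE = dict(grid_dims=(8, 8, 6), n_per_group=16, roi_specs=(),
                univariate_shift=0.0, pattern_amplitude=0.0)

    def test_equal_variances_give_symmetric_errors(self):
        cfgs = [SyntheticConfig(**self.BASE, noise_sd_control=1.0, noise_sd_patient=1.0)]
        tab = variance_asymmetry_experiment(cfgs, n_reps=30, seed=2,
                                            solver=SolverConfig(max_iter=300))
        gap = tab.iloc[0]["mean_sensitivity"] - tab.iloc[0]["mean_specificity"]
        assert abs(gap) < 5.0

    def test_rejects_configs_differing_beyond_noise_shape(self):
        cfgs = [
            SyntheticConfig(**self.BASE),
            SyntheticConfig(**{**self.BASE, "n_per_group": 8}),
        ]
        with pytest.raises(ValueError, match="noise shape"):
            variance_asymmetry_experiment(cfgs, n_reps=2, seed=0)

    def test_rejects_single_rep(self):
        with pytest.raises(ValueError, match="n_reps"):
            variance_asymmetry_experiment([SyntheticConfig(**self.BASE)], n_reps=1, seed=0)


class TestCohortIO:
    def test_written_cohort_reloads_consistently(self, tmp_path):
        cfg = SyntheticConfig(grid_dims=(8, 8, 6), n_per_group=3, roi_specs=(), seed=5)
        c = generate_cohort(cfg)
        generate_symptom_scores(c, cfg)
        write_cohort(c, tmp_path)
        table = read_cohort_table(tmp_path / "cohort.csv")
        assert len(table) == 6
        assert set(table.columns) >= {"subject_id", "group", "age", "sex",
                                      "smoker", "panss_negative", "label"}
        assert (tmp_path / "ground_truth.json").exists()
        from rewardlight.volumes import read_nifti

        v, grid = read_nifti(tmp_path / f"{c.stack.subject_ids[0]}.nii.gz")
        assert np.abs(v - c.stack.data[0]).max() < 1e-5
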