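"""Leave-one-subject-out searchlight decoding."""

import numpy as np
import pytest

from rewardlight import _kernels
from rewardlight.searchlight import (
    confusion_metrics,
    loocv_predict_labels,
    run_searchlight_svc,
)
from rewardlight.svm import SolverConfig
from rewardlight.volumes import (
    MaskVolume,
    SearchlightSpec,
    SubjectVolumeStack,
    VoxelGrid,
    searchlight_neighbors,
)


class TestLoocv:
    def test_perfect_separation_predicts_everyone(self, separable_features):
        X, labels = separable_features
        preds = loocv_predict_labels(X, labels, SolverConfig(max_iter=2000, seed=0))
        assert np.array_equal(preds, labels)

    def test_pure_noise_mean_accuracy_slightly_below_chance(self, rng):
        # leaving one subject out makes the opposite class the training
        # majority, biasing predictions against the held-out subject
        accs = []
        n = 10
        labels = np.concatenate([np.ones(n, dtype=int), -np.ones(n, dtype=int)])
        for rep in range(40):
            X = rng.standard_normal((2 * n, 5))
            preds = loocv_predict_labels(X, labels, SolverConfig(max_iter=500, seed=rep))
            accs.append((preds == labels).mean())
        mean_acc = np.mean(accs)
        assert 0.30 < mean_acc < 0.50

    def test_rerun_is_identical(self, rng):
        X = rng.standard_normal((12, 6))
        labels = np.concatenate([np.ones(6, dtype=int), -np.ones(6, dtype=int)])
        cfg = SolverConfig(max_iter=1000, seed=9)
        assert np.array_equal(
            loocv_predict_labels(X, labels, cfg), loocv_predict_labels(X, labels, cfg)
        )

    def test_kernel_folds_match_python_reimplementation(self, rng):
        # independent check that fold j trains without subject j: rebuild
        # each fold in numpy with the same derived seed and compare exactly
        X = rng.standard_normal((8, 3))
        labels = np.concatenate([np.ones(4), -np.ones(4)])
        C, T, seed = 1.0, 400, 77
        scores = _kernels.loocv_svc_scores(X, labels, C, T, np.uint64(seed), True)
        Xb = np.hstack([X, np.ones((8, 1))])
        lam = 1.0 / (7 * C)
        for j in range(8):
            keep = np.arange(8) != j
            seed_j = np.uint64(_kernels.derive_seed(np.uint64(seed), np.uint64(j), np.uint64(0)))
            w = _kernels.pegasos_svc(
                np.ascontiguousarray(Xb[keep]), labels[keep], lam, T, seed_j,
                False, True,
            )
            assert scores[j] == pytest.approx(float(w @ Xb[j]), rel=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            loocv_predict_labels(np.zeros((3, 1)), np.array([1, -1, 1]), SolverConfig())

    def test_singleton_class_rejected(self):
        X = np.zeros((5, 1))
        labels = np.array([1, -1, -1, -1, -1])
        with pytest.raises(ValueError, match="per class"):
            loocv_predict_labels(X, labels, SolverConfig())


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "preds,truth,expected",
        [
            ([1, 1, -1, -1], [1, 1, -1, -1], (100.0, 100.0, 100.0)),
            ([1, 1, 1, 1], [1, 1, -1, -1], (50.0, 100.0, 0.0)),
        ],
    )
    def test_hand_cases(self, preds, truth, expected):
        assert confusion_metrics(np.array(preds), np.array(truth)) == expected

    def test_peak_row_arithmetic_matches_report_format(self, rng):
        # 43 of 44 patients and 39 of 44 controls correct -> 93.2% accuracy
        truth = np.concatenate([np.ones(44, dtype=int), -np.ones(44, dtype=int)])
        preds = truth.copy()
        preds[0] = -1
        wrong_controls = 44 + rng.choice(44, size=5, replace=False)
        preds[wrong_controls] = 1
        acc, sens, spec = confusion_metrics(preds, truth)
        assert acc == pytest.approx(93.2, abs=0.05)
        assert sens == pytest.approx(97.7, abs=0.05)
        assert spec == pytest.approx(88.6, abs=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([]), np.array([]))


def _stack_from_features(grid, features, rng):
    """Embed per-subject feature values at distinct voxels of a volume."""
    n = features.shape[0]
    data = rng.standard_normal((n, *grid.dims))
    return SubjectVolumeStack(grid, [f"s{i}" for i in range(n)], data)


class TestSearchlightMaps:
    def test_single_voxel_mask_reduces_to_loocv(self, rng):
        grid = VoxelGrid((7, 7, 5))
        n = 12
        labels = np.concatenate([np.ones(6, dtype=int), -np.ones(6, dtype=int)])
        stack = _stack_from_features(grid, np.empty((n, 0)), rng)
        m = np.zeros(grid.dims, dtype=bool)
        m[3, 3, 2] = True
        mask = MaskVolume(grid, m, "one")
        spec = SearchlightSpec(2)
        solver = SolverConfig(max_iter=500)
        res = run_searchlight_svc(stack, labels, mask, spec, solver, seed=5)
        nb = searchlight_neighbors(
            (3, 3, 2), spec, MaskVolume(grid, np.ones(grid.dims, bool), "full")
        )
        feats = stack.data[:, nb[:, 0], nb[:, 1], nb[:, 2]]
        seed_v = np.uint64(_kernels.derive_seed(np.uint64(5), np.uint64(0), np.uint64(0)))
        scores = _kernels.loocv_svc_scores(
            np.ascontiguousarray(feats), labels.astype(float), solver.C,
            solver.n_iter(n - 1), seed_v, True,
        )
        expected = np.where(scores >= 0, 1, -1)
        assert np.array_equal(res.predictions[0], expected)
        acc = 100.0 * (expected == labels).mean()
        assert res.accuracy.data[3, 3, 2] == pytest.approx(acc)

    def test_maps_consistent_with_retained_predictions(self, rng):
        grid = VoxelGrid((8, 8, 6))
        n = 16
        labels = np.concatenate([np.ones(8, dtype=int), -np.ones(8, dtype=int)])
        stack = _stack_from_features(grid, np.empty((n, 0)), rng)
        m = np.zeros(grid.dims, dtype=bool)
        m[2:6, 2:6, 2:4] = True
        mask = MaskVolume(grid, m, "box")
        res = run_searchlight_svc(
            stack, labels, mask, SearchlightSpec(2), SolverConfig(max_iter=300), seed=1
        )
        for i, c in enumerate(res.centers):
            acc, sens, spec = confusion_metrics(res.predictions[i], labels)
            assert res.accuracy.data[tuple(c)] == pytest.approx(acc)
            assert res.sensitivity.data[tuple(c)] == pytest.approx(sens)
            assert res.specificity.data[tuple(c)] == pytest.approx(spec)
        outside = ~mask.data
        assert np.isnan(res.accuracy.data[outside]).all()

    def test_balanced_metrics_average_to_accuracy_for_equal_groups(self):
        truth = np.concatenate([np.ones(6, dtype=int), -np.ones(6, dtype=int)])
        preds = truth.copy()
        preds[[0, 6]] *= -1  # one symmetric error per class
        acc, sens, spec = confusion_metrics(preds, truth)
        assert (sens + spec) / 2 == pytest.approx(acc)

    def test_nan_in_sphere_skips_voxel(self, rng):
        grid = VoxelGrid((7, 7, 5))
        n = 12
        labels = np.concatenate([np.ones(6, dtype=int), -np.ones(6, dtype=int)])
        data = rng.standard_normal((n, *grid.dims))
        data[0, 3, 3, 2] = np.nan
        m = np.zeros(grid.dims, dtype=bool)
        m[2:5, 2:5, 1:4] = True
        m[3, 3, 2] = False  # keep the stack mask-finite; sphere still reaches it
        mask = MaskVolume(grid, m, "box")
        stack = SubjectVolumeStack(grid, [f"s{i}" for i in range(n)], data, mask)
        res = run_searchlight_svc(
            stack, labels, mask, SearchlightSpec(2), SolverConfig(max_iter=200), seed=0
        )
        assert res.skipped.sum() > 0
        assert np.isnan(res.accuracy.data[3, 3, 1])

    def test_mask_grid_mismatch_rejected(self, rng):
        grid = VoxelGrid((7, 7, 5))
        stack = _stack_from_features(grid, np.empty((4, 0)), rng)
        other = VoxelGrid((6, 6, 4))
        mask = MaskVolume(other, np.ones(other.dims, bool), "m")
        with pytest.raises(ValueError, match="grid"):
            run_searchlight_svc(
                stack, np.array([1, 1, -1, -1]), mask, SearchlightSpec(2),
                SolverConfig(), seed=0,
            )
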