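"""Leave-one-subject-out searchlight SVC decoding.

For every voxel of the analysis mask, the subject values within the
searchlight sphere centred there form the feature vectors of a linear SVC
trained and evaluated under a leave-one-subject-out scheme: each of the N
subjects is predicted once by a model trained on the other N-1.  Training
folds are left unbalanced (e.g. 43 vs 44 per fold for equal groups), as the
small imbalance alternates sides across folds.  The fraction of correct
predictions — plus sensitivity (patients) and specificity (controls) — is
mapped to the sphere's center, yielding whole-volume decoding maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .svm import SolverConfig
from .volumes import (
    MaskVolume,
    SearchlightSpec,
    StatMap,
    SubjectVolumeStack,
    neighbor_table,
    write_nifti,
)

__all__ = [
    "DecodingResult",
    "loocv_predict_labels",
    "confusion_metrics",
    "run_searchlight_svc",
]


def _validate_labels(labels: np.ndarray, min_per_class: int = 2) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be +1 (patient) / -1 (control)")
    labels = labels.astype(np.float64)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    if min(n_pos, n_neg) < min_per_class:
        raise ValueError(
            f"need at least {min_per_class} subjects per class, got {n_pos}/{n_neg}"
        )
    return labels


def loocv_predict_labels(
    features: np.ndarray, labels: np.ndarray, config: SolverConfig
) -> np.ndarray:
    """One predicted label per subject, each from a model trained without it.

    Raises if any leave-one-out training fold would contain a single class
    (i.e. a class with only one member overall).
    """
    X = np.ascontiguousarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be (n_subjects, d)")
    labels = _validate_labels(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("features/labels length mismatch")
    if X.shape[0] < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    n = X.shape[0]
    scores = _kernels.loocv_svc_scores(
        X, labels, config.C, config.n_iter(n - 1), np.uint64(config.seed), config.use_bias
    )
    return np.where(scores >= 0.0, 1, -1)


def confusion_metrics(predictions, truth) -> tuple[float, float, float]:
    """(accuracy %, sensitivity %, specificity %); patients (+1) positive.

    Sensitivity is the fraction of patients predicted patient, specificity
    the fraction of controls predicted control.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.size == 0:
        raise ValueError("empty prediction vector")
    if predictions.shape != truth.shape:
        raise ValueError("predictions/truth length mismatch")
    if not np.all(np.isin(truth, (-1, 1))):
        raise ValueError("truth labels must be +1/-1")
    correct = predictions == truth
    acc = 100.0 * correct.mean()
    pos = truth == 1
    neg = ~pos
    sens = 100.0 * correct[pos].mean() if pos.any() else np.nan
    spec = 100.0 * correct[neg].mean() if neg.any() else np.nan
    return float(acc), float(sens), float(spec)


@dataclass
class DecodingResult:
    """Searchlight LOOCV decoding maps plus retained fold predictions."""

    accuracy: StatMap
    sensitivity: StatMap
    specificity: StatMap
    predictions: np.ndarray  # (n_mask_voxels, n_subjects), +1/-1, NaN-skipped rows = 0
    centers: np.ndarray  # (n_mask_voxels, 3)
    skipped: np.ndarray  # bool, centers skipped due to non-finite sphere values
    spec: SearchlightSpec
    solver: SolverConfig
    seed: int
    subject_ids: list[str]
    labels: np.ndarray

    def predictions_at(self, center) -> np.ndarray:
        """Retained per-subject predicted labels at a mask voxel."""
        hit = np.flatnonzero((self.centers == np.asarray(center)).all(axis=1))
        if hit.size == 0:
            raise ValueError(f"{tuple(center)} is not a mask voxel")
        return self.predictions[hit[0]]

    def write(self, out_dir) -> None:
        """Write accuracy/sensitivity/specificity NIfTI maps + run manifest."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m in (self.accuracy, self.sensitivity, self.specificity):
            write_nifti(out / f"{m.name}.nii.gz", m.data, m.grid)
        manifest = {
            "seed": int(self.seed),
            "searchlight_diameter_voxels": self.spec.diameter_voxels,
            "restrict_to_mask": self.spec.restrict_to_mask,
            "solver": {
                "C": self.solver.C,
                "max_iter": self.solver.max_iter,
                "use_bias": self.solver.use_bias,
                "epsilon_solution": self.solver.epsilon_solution,
            },
            "n_subjects": len(self.subject_ids),
            "n_mask_voxels": int(self.centers.shape[0]),
            "n_skipped": int(self.skipped.sum()),
        }
        (out / "searchlight_svc_manifest.json").write_text(json.dumps(manifest, indent=2))


def run_searchlight_svc(
    stack: SubjectVolumeStack,
    labels: np.ndarray,
    mask: MaskVolume,
    spec: SearchlightSpec,
    solver: SolverConfig,
    seed: int,
) -> DecodingResult:
    """LOOCV SVC in a sphere around every mask voxel; maps % metrics.

    Results are independent of voxel processing order: the per-voxel solver
    seed is derived from the master seed and the voxel's index.
    """
    labels = _validate_labels(labels)
    if stack.n_subjects != labels.shape[0]:
        raise ValueError("stack/labels length mismatch")
    if not mask.grid.compatible(stack.grid):
        raise ValueError("mask grid does not match volume stack grid")
    centers, neigh_flat, neigh_ptr = neighbor_table(mask, spec)
    n = stack.n_subjects
    scores = _kernels.searchlight_svc_scores(
        stack.flat(), labels, neigh_flat, neigh_ptr,
        solver.C, solver.n_iter(n - 1), np.uint64(seed), solver.use_bias,
        np.uint64(0),
    )
    skipped = ~np.isfinite(scores).all(axis=1)
    preds = np.where(scores >= 0.0, 1, -1)
    preds[skipped] = 0

    dims = mask.grid.dims
    maps = {k: np.full(dims, np.nan) for k in ("accuracy", "sensitivity", "specificity")}
    correct = preds == labels[None, :]
    pos = labels == 1
    cidx = tuple(centers.T)
    acc = 100.0 * correct.mean(axis=1)
    sens = 100.0 * correct[:, pos].mean(axis=1)
    spc = 100.0 * correct[:, ~pos].mean(axis=1)
    for arr, key in ((acc, "accuracy"), (sens, "sensitivity"), (spc, "specificity")):
        vals = arr.astype(float)
        vals[skipped] = np.nan
        maps[key][cidx] = vals
    return DecodingResult(
        accuracy=StatMap(mask.grid, maps["accuracy"], "accuracy"),
        sensitivity=StatMap(mask.grid, maps["sensitivity"], "sensitivity"),
        specificity=StatMap(mask.grid, maps["specificity"], "specificity"),
        predictions=preds,
        centers=centers,
        skipped=skipped,
        spec=spec,
        solver=solver,
        seed=seed,
        subject_ids=list(stack.subject_ids),
        labels=labels.astype(int),
    )
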