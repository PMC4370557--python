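"""Searchlight support-vector regression of negative-symptom severity.

Within an ROI mask (the ventral striatum in the original design), a linear
epsilon-insensitive SVR (C = 1) is trained in a sphere of four voxels in
diameter around every ROI voxel, under leave-one-patient-out
cross-validation: the held-out patient's symptom score is predicted from
their contrast pattern alone.  The Spearman correlation between predicted
and actual scores is mapped to the sphere center.  The chance level is
obtained by re-running the whole procedure with the symptom scores
randomly reassigned across patients (one global reassignment per
iteration); predictions of a null model are still evaluated against the
true scores, so negative chance correlations are the norm — a null SVR
carries no predictive information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from . import _kernels
from .inference import PermutationConfig, PermutationNull
from .svm import SolverConfig
from .volumes import (
    MaskVolume,
    SearchlightSpec,
    StatMap,
    SubjectVolumeStack,
    neighbor_table,
)

__all__ = ["SvrMapResult", "spearman_rho", "run_searchlight_svr", "build_null_svr"]

SVR_DEFAULT_SPEC = SearchlightSpec(diameter_voxels=4, restrict_to_mask=True)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (an explicit degenerate result) when either vector is
    constant, where rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be aligned 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def _rho_rows(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Spearman rho of each prediction row against the actual scores."""
    out = np.full(pred.shape[0], np.nan)
    for i in range(pred.shape[0]):
        row = pred[i]
        if np.isfinite(row).all():
            out[i] = spearman_rho(row, actual)
    return out


@dataclass
class SvrMapResult:
    """Per-voxel Spearman rho map plus retained prediction vectors."""

    rho: StatMap
    predictions: np.ndarray  # (n_centers, n_patients)
    centers: np.ndarray
    scores: np.ndarray  # actual symptom scores, patient order
    spec: SearchlightSpec
    solver: SolverConfig
    seed: int

    def predictions_at(self, center) -> np.ndarray:
        hit = np.flatnonzero((self.centers == np.asarray(center)).all(axis=1))
        if hit.size == 0:
            raise ValueError(f"{tuple(center)} is not an ROI voxel")
        return self.predictions[hit[0]]

    def peak(self):
        """(center index triple, rho) of the best-predicting sphere."""
        vals = np.where(np.isfinite(self.rho.data), self.rho.data, -np.inf)
        flat = int(np.argmax(vals))
        idx = np.unravel_index(flat, vals.shape)
        return tuple(int(i) for i in idx), float(self.rho.data[idx])


def _validate(patient_stack: SubjectVolumeStack, scores, roi_mask: MaskVolume):
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (patient_stack.n_subjects,):
        raise ValueError("scores must align with the patient stack")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite symptom scores")
    if patient_stack.n_subjects < 4:
        raise ValueError("need at least 4 patients for the LOOCV searchlight")
    if not roi_mask.grid.compatible(patient_stack.grid):
        raise ValueError("ROI mask grid does not match patient stack grid")
    return scores


def run_searchlight_svr(
    patient_stack: SubjectVolumeStack,
    scores,
    roi_mask: MaskVolume,
    spec: SearchlightSpec = SVR_DEFAULT_SPEC,
    solver: SolverConfig | None = None,
    seed: int = 0,
) -> SvrMapResult:
    """Leave-one-patient-out SVR in a sphere around every ROI voxel.

    Maps the Spearman correlation between LOOCV-predicted and actual
    scores to each sphere center.
    """
    solver = solver or SolverConfig(C=1.0)
    scores = _validate(patient_stack, scores, roi_mask)
    centers, neigh_flat, neigh_ptr = neighbor_table(roi_mask, spec)
    n = patient_stack.n_subjects
    preds = _kernels.searchlight_svr_predictions(
        patient_stack.flat(), scores, neigh_flat, neigh_ptr,
        solver.C, solver.epsilon_tube, solver.n_iter(n - 1),
        np.uint64(seed), solver.use_bias, np.uint64(0),
    )
    rho = _rho_rows(preds, scores)
    out = np.full(roi_mask.grid.dims, np.nan)
    out[tuple(centers.T)] = rho
    return SvrMapResult(
        rho=StatMap(roi_mask.grid, out, "svr_spearman_rho"),
        predictions=preds,
        centers=centers,
        scores=scores,
        spec=spec,
        solver=solver,
        seed=seed,
    )


def build_null_svr(
    patient_stack: SubjectVolumeStack,
    scores,
    roi_mask: MaskVolume,
    spec: SearchlightSpec = SVR_DEFAULT_SPEC,
    solver: SolverConfig | None = None,
    perm_config: PermutationConfig = PermutationConfig(scheme="symptom_scores"),
) -> PermutationNull:
    """Chance rho distribution from score-reassignment null SVR models.

    Each iteration draws one random reassignment of patient indices, runs
    the full LOOCV searchlight with the training scores permuted under it
    (patched per fold so that each training set carries exactly the
    training patients' own scores, reassigned — the held-out patient's
    true score never enters training), and correlates the resulting
    predictions with the *true* scores.  Because a null fold's training
    scores exclude the held-out score, predictions anticorrelate slightly
    with the actual scores, so the chance rho distribution is centred at
    or below zero — a null SVR model carries no predictive information.
    """
    solver = solver or SolverConfig(C=1.0)
    scores = _validate(patient_stack, scores, roi_mask)
    if perm_config.scheme != "symptom_scores":
        raise ValueError("SVR null requires the symptom_scores permutation scheme")
    centers, neigh_flat, neigh_ptr = neighbor_table(roi_mask, spec)
    n = patient_stack.n_subjects
    n_iter = solver.n_iter(n - 1)
    data_flat = patient_stack.flat()
    rng = np.random.default_rng(perm_config.seed)
    identity = np.arange(n)
    samples = np.empty((perm_config.n_perm, centers.shape[0]), dtype=np.float32)
    for p in range(perm_config.n_perm):
        while True:
            perm = rng.permutation(n)
            if not np.array_equal(perm, identity):
                break
        preds = _kernels.searchlight_svr_null_predictions(
            data_flat, scores, perm.astype(np.int64), neigh_flat, neigh_ptr,
            solver.C, solver.epsilon_tube, n_iter,
            np.uint64(perm_config.seed), solver.use_bias, np.uint64(p + 1),
        )
        samples[p] = _rho_rows(preds, scores)
    return PermutationNull(samples, centers, perm_config.seed, "symptom_scores")
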