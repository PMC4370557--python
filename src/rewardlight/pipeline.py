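"""End-to-end orchestration: simulate -> decode -> test -> report.

``run_full_pipeline`` chains the package's stages on a synthetic cohort:
cohort generation, searchlight SVC decoding with a label-permutation null,
FDR + cluster-extent thresholding, the univariate t / ROC baseline with
McNemar comparison at the ventral-striatum peaks, the symptom SVR
searchlight with its score-reassignment null, and the report tables.  A
single master seed drives every stage; re-running with the same config
reproduces every output bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import (
    PermutationConfig,
    PermutationNull,
    build_null_svc,
    cluster_filter,
    fdr_bh,
    generate_label_permutations,
    pvalue_map,
)
from .reporting import cohort_summary, peak_table
from .searchlight import DecodingResult, run_searchlight_svc
from .svm import SolverConfig
from .symptoms import SvrMapResult, build_null_svr, run_searchlight_svr
from .synthetic import (
    CohortDataset,
    RoiSpec,
    SyntheticConfig,
    generate_cohort,
    generate_roi_mask,
    generate_symptom_scores,
    write_cohort,
)
from .univariate import (
    _max_accuracy_fraction,
    mcnemar_test,
    roc_max_accuracy,
    run_roc_accuracy_map,
    voxelwise_t_map,
)
from .volumes import MaskVolume, SearchlightSpec, StatMap, write_nifti

__all__ = ["PipelineConfig", "PipelineResult", "demo_config", "run_full_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full synthetic-cohort analysis run."""

    synthetic: SyntheticConfig
    analysis_mask: RoiSpec
    svr_roi: str = "ventral_striatum"
    svc_spec: SearchlightSpec = SearchlightSpec(diameter_voxels=6)
    svr_spec: SearchlightSpec = SearchlightSpec(diameter_voxels=4, restrict_to_mask=True)
    svc_solver: SolverConfig = field(default_factory=lambda: SolverConfig(max_iter=200))
    svr_solver: SolverConfig = field(default_factory=lambda: SolverConfig(C=1.0, max_iter=200))
    n_perm: int = 199
    q: float = 0.05
    min_cluster_size: int = 30
    connectivity: int = 18
    seed: int = 0

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_perm": self.n_perm,
            "q": self.q,
            "min_cluster_size": self.min_cluster_size,
            "connectivity": self.connectivity,
            "svc_diameter": self.svc_spec.diameter_voxels,
            "svr_diameter": self.svr_spec.diameter_voxels,
            "svc_max_iter": self.svc_solver.max_iter,
            "svr_max_iter": self.svr_solver.max_iter,
            "svr_roi": self.svr_roi,
            "synthetic": {
                "grid_dims": list(self.synthetic.grid_dims),
                "voxel_size_mm": self.synthetic.voxel_size_mm,
                "n_per_group": self.synthetic.n_per_group,
                "univariate_shift": self.synthetic.univariate_shift,
                "pattern_amplitude": self.synthetic.pattern_amplitude,
                "noise_sd_control": self.synthetic.noise_sd_control,
                "noise_sd_patient": self.synthetic.noise_sd_patient,
                "smoothing_fwhm": self.synthetic.smoothing_fwhm,
                "seed": self.synthetic.seed,
            },
        }


def demo_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale demo: 20x20x12 grid, 2x22 subjects, 199 permutations.

    The analysis mask is a 179-voxel central sphere; the symptom SVR runs
    in the 93-voxel ventral-striatum stand-in ROI with a diameter-4
    sphere.  Solvers use 200 Pegasos steps per fold and the cluster-extent
    threshold is scaled to 10 voxels to match the reduced volume.
    """
    syn = SyntheticConfig(
        grid_dims=(20, 20, 12),
        n_per_group=22,
        roi_specs=(RoiSpec((10, 10, 6), 2.83, "ventral_striatum"),),
        univariate_shift=0.25,
        pattern_amplitude=0.5,
        expression_sd=0.75,
        seed=seed,
    )
    return PipelineConfig(
        synthetic=syn,
        analysis_mask=RoiSpec((10, 10, 6), 3.5, "analysis"),
        n_perm=199,
        min_cluster_size=10,
        seed=seed,
    )


@dataclass
class PipelineResult:
    """All stage outputs of one full run."""

    cohort: CohortDataset
    analysis_mask: MaskVolume
    roi_mask: MaskVolume
    decoding: DecodingResult
    svc_null: PermutationNull
    svc_p: StatMap
    svc_sig: np.ndarray
    svc_fdr_threshold: float
    svc_clusters: pd.DataFrame
    svc_peak_table: pd.DataFrame
    t_map: StatMap
    roc_map: StatMap
    roc_null: PermutationNull
    roc_p: StatMap
    roc_sig: np.ndarray
    mcnemar: object
    svc_roi_peak: tuple
    roc_roi_peak: tuple
    svr: SvrMapResult
    svr_null: PermutationNull
    svr_p: StatMap
    svr_sig: np.ndarray
    summary: object
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def _build_roc_null(stack, labels, mask, perm_config: PermutationConfig) -> PermutationNull:
    """ROC max-accuracy chance maps under the SVC label permutations."""
    perms = generate_label_permutations(labels, perm_config.n_perm, perm_config.seed)
    vals = stack.flat()[:, mask.data.reshape(-1)]
    centers = mask.indices()
    samples = np.empty((perm_config.n_perm, vals.shape[1]), dtype=np.float32)
    for p in range(perm_config.n_perm):
        y = perms[p]
        for j in range(vals.shape[1]):
            samples[p, j] = 100.0 * _max_accuracy_fraction(vals[:, j], y)
    return PermutationNull(samples, centers, perm_config.seed, "labels")


def run_full_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run every stage; optionally write maps/tables/manifest to ``out_dir``."""
    grid = config.synthetic.grid()

    @_stage("simulate")
    def simulate():
        cohort = generate_cohort(config.synthetic)
        scores = generate_symptom_scores(cohort, config.synthetic)
        return cohort, scores

    cohort, scores = simulate()

    @_stage("masks")
    def masks():
        analysis = generate_roi_mask(config.analysis_mask, grid, name="analysis")
        roi_spec = {r.name: r for r in config.synthetic.roi_specs}.get(config.svr_roi)
        if roi_spec is None:
            raise ValueError(f"SVR ROI {config.svr_roi!r} not among synthetic ROIs")
        roi = generate_roi_mask(roi_spec, grid)
        return analysis, roi

    analysis_mask, roi_mask = masks()

    @_stage("searchlight-svc")
    def svc():
        return run_searchlight_svc(
            cohort.stack, cohort.labels, analysis_mask,
            config.svc_spec, config.svc_solver, config.seed,
        )

    decoding = svc()

    @_stage("permtest")
    def permtest():
        pc = PermutationConfig(n_perm=config.n_perm, seed=config.seed + 1, scheme="labels")
        null = build_null_svc(
            cohort.stack, cohort.labels, analysis_mask,
            config.svc_spec, config.svc_solver, pc,
        )
        pmap = pvalue_map(decoding.accuracy, null, analysis_mask)
        pvals = pmap.data[analysis_mask.data]
        reject, thr = fdr_bh(pvals, config.q)
        sig = np.zeros(grid.dims, dtype=bool)
        sig[analysis_mask.data] = reject
        clusters, filtered = cluster_filter(
            sig, config.min_cluster_size, config.connectivity, stat_map=decoding.accuracy
        )
        ptable = peak_table(
            decoding.accuracy, filtered, clusters,
            {"sensitivity": decoding.sensitivity, "specificity": decoding.specificity},
            null,
        )
        return null, pmap, filtered, thr, clusters, ptable

    svc_null, svc_p, svc_sig, svc_thr, svc_clusters, svc_ptable = permtest()

    @_stage("univariate")
    def univar():
        tmap = voxelwise_t_map(cohort.stack, cohort.labels, analysis_mask)
        roc_map = run_roc_accuracy_map(cohort.stack, cohort.labels, analysis_mask)
        pc = PermutationConfig(n_perm=config.n_perm, seed=config.seed + 1, scheme="labels")
        roc_null = _build_roc_null(cohort.stack, cohort.labels, analysis_mask, pc)
        roc_p = pvalue_map(roc_map, roc_null, analysis_mask)
        reject, _ = fdr_bh(roc_p.data[analysis_mask.data], config.q)
        roc_sig = np.zeros(grid.dims, dtype=bool)
        roc_sig[analysis_mask.data] = reject

        # McNemar at each method's ROI peak: searchlight LOOCV correctness
        # vs the in-sample ROC assignment correctness
        svc_peak, svc_peak_acc = decoding.accuracy.peak(roi_mask)
        roc_peak, roc_peak_acc = roc_map.peak(roi_mask)
        svc_correct = decoding.predictions_at(svc_peak) == cohort.labels
        roc_vals = cohort.stack.data[:, roc_peak[0], roc_peak[1], roc_peak[2]]
        rr = roc_max_accuracy(roc_vals, cohort.labels)
        above = roc_vals > rr.threshold
        roc_pred = np.where(above, rr.direction, -rr.direction)
        roc_correct = roc_pred == cohort.labels
        mc = mcnemar_test(svc_correct, roc_correct)
        return (tmap, roc_map, roc_null, roc_p, roc_sig, mc,
                (svc_peak, svc_peak_acc), (roc_peak, roc_peak_acc))

    t_map, roc_map, roc_null, roc_p, roc_sig, mc, svc_roi_peak, roc_roi_peak = univar()

    @_stage("svr-symptoms")
    def svr():
        pstack = cohort.patient_stack()
        res = run_searchlight_svr(
            pstack, scores, roi_mask, config.svr_spec, config.svr_solver, config.seed
        )
        pc = PermutationConfig(
            n_perm=config.n_perm, seed=config.seed + 2, scheme="symptom_scores"
        )
        null = build_null_svr(pstack, scores, roi_mask, config.svr_spec,
                              config.svr_solver, pc)
        pmap = pvalue_map(res.rho, null, roi_mask)
        reject, _ = fdr_bh(pmap.data[roi_mask.data], config.q)
        sig = np.zeros(grid.dims, dtype=bool)
        sig[roi_mask.data] = reject
        return res, null, pmap, sig

    svr_res, svr_null, svr_p, svr_sig = svr()

    @_stage("report")
    def report():
        summ = cohort_summary(cohort.table, numeric_fields=("age",),
                              categorical_fields=("sex", "smoker"))
        manifest = {
            "config": config.to_dict(),
            "stages": ["simulate", "masks", "searchlight-svc", "permtest",
                       "univariate", "svr-symptoms", "report"],
            "n_analysis_voxels": int(analysis_mask.n_voxels),
            "n_roi_voxels": int(roi_mask.n_voxels),
            "svc_fdr_threshold": float(svc_thr),
            "svc_chance_summary": svc_null.summary(),
            "svr_chance_summary": svr_null.summary(),
            "svc_roi_peak": {"voxel": list(svc_roi_peak[0]), "accuracy": svc_roi_peak[1]},
            "roc_roi_peak": {"voxel": list(roc_roi_peak[0]), "accuracy": roc_roi_peak[1]},
            "svr_peak": {"voxel": list(svr_res.peak()[0]), "rho": svr_res.peak()[1]},
            "mcnemar": {"statistic": mc.statistic, "p": mc.p, "b": mc.b, "c": mc.c,
                        "degenerate": mc.degenerate},
        }
        return summ, manifest

    summary, manifest = report()

    result = PipelineResult(
        cohort=cohort, analysis_mask=analysis_mask, roi_mask=roi_mask,
        decoding=decoding, svc_null=svc_null, svc_p=svc_p, svc_sig=svc_sig,
        svc_fdr_threshold=svc_thr, svc_clusters=svc_clusters,
        svc_peak_table=svc_ptable, t_map=t_map, roc_map=roc_map,
        roc_null=roc_null, roc_p=roc_p, roc_sig=roc_sig, mcnemar=mc,
        svc_roi_peak=svc_roi_peak, roc_roi_peak=roc_roi_peak,
        svr=svr_res, svr_null=svr_null, svr_p=svr_p, svr_sig=svr_sig,
        summary=summary, manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(res: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = res.analysis_mask.grid
    # .nii (uncompressed) keeps outputs byte-stable across re-runs
    for m in (res.decoding.accuracy, res.decoding.sensitivity,
              res.decoding.specificity, res.svc_p, res.t_map, res.roc_map,
              res.roc_p, res.svr.rho, res.svr_p):
        write_nifti(out / f"{m.name}.nii", m.data, m.grid)
    write_nifti(out / "svc_significant.nii", res.svc_sig.astype(np.float32), grid)
    write_nifti(out / "roc_significant.nii", res.roc_sig.astype(np.float32), grid)
    write_nifti(out / "svr_significant.nii", res.svr_sig.astype(np.float32), grid)
    res.svc_clusters.to_csv(out / "svc_clusters.tsv", sep="\t", index=False)
    res.svc_peak_table.to_csv(out / "svc_peak_table.tsv", sep="\t", index=False)
    res.summary.numeric.to_csv(out / "cohort_numeric.tsv", sep="\t", index=False)
    res.summary.categorical.to_csv(out / "cohort_categorical.tsv", sep="\t", index=False)
    # peak scatter: actual vs predicted symptom scores at the SVR peak
    peak_idx, _ = res.svr.peak()
    pd.DataFrame(
        {"actual": res.svr.scores, "predicted": res.svr.predictions_at(peak_idx)}
    ).to_csv(out / "svr_peak_scatter.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(res.manifest, indent=2, sort_keys=True))
    write_cohort(res.cohort, out / "cohort")
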