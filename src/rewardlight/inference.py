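"""Permutation nulls, empirical p-values, FDR control and cluster filtering.

Voxelwise significance of the decoding maps is assessed non-parametrically:
the group labels are randomly permuted, the entire LOOCV searchlight is
re-run under each permutation (one global relabelling per iteration, shared
by every voxel, which preserves the spatial coherence of the null maps),
and the per-voxel chance histograms yield right-tailed empirical p-values
with the plus-one estimator p = (1 + #{null >= observed}) / (n_perm + 1).
Multiplicity is controlled by Benjamini-Hochberg FDR, and surviving voxels
are filtered by a minimum cluster extent (30 voxels at study scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _kernels
from .svm import SolverConfig
from .volumes import MaskVolume, SearchlightSpec, StatMap, SubjectVolumeStack, neighbor_table

__all__ = [
    "PermutationConfig",
    "PermutationNull",
    "generate_label_permutations",
    "build_null_svc",
    "empirical_pvalue",
    "pvalue_map",
    "fdr_bh",
    "cluster_filter",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings.

    ``n_perm`` is 10,000 at study scale; desk-scale runs use a few hundred.
    ``scheme`` records what is being permuted (diagnosis labels or symptom
    scores).  ``score_against_permuted`` scores null predictions against
    the permuted labels (full exchangeability); the alternative scores
    against the true labels.
    """

    n_perm: int = 200
    seed: int = 0
    scheme: str = "labels"
    score_against_permuted: bool = True

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.scheme not in ("labels", "symptom_scores"):
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")


@dataclass
class PermutationNull:
    """Per-voxel chance-statistic samples from label/score permutations."""

    samples: np.ndarray  # (n_perm, n_centers)
    centers: np.ndarray  # (n_centers, 3)
    seed: int
    scheme: str

    @property
    def n_perm(self) -> int:
        return self.samples.shape[0]

    def voxel_min_mean_max(self) -> np.ndarray:
        """(n_centers, 3) per-voxel chance minimum / mean / maximum."""
        return np.stack(
            [self.samples.min(axis=0), self.samples.mean(axis=0), self.samples.max(axis=0)],
            axis=1,
        )

    def summary(self) -> dict:
        """Across-voxel means of the per-voxel chance min/mean/max.

        This is the "lowest, medium and highest chance score" summary the
        peak tables report.
        """
        m = self.voxel_min_mean_max()
        return {
            "mean_min": float(m[:, 0].mean()),
            "mean_mean": float(m[:, 1].mean()),
            "mean_max": float(m[:, 2].mean()),
        }

    def at_center(self, center) -> np.ndarray:
        """Chance samples at one mask voxel."""
        hit = np.flatnonzero((self.centers == np.asarray(center)).all(axis=1))
        if hit.size == 0:
            raise ValueError(f"{tuple(center)} not in null support")
        return self.samples[:, hit[0]]


def generate_label_permutations(labels, n_perm: int, seed: int) -> np.ndarray:
    """Random global relabellings of the label vector, identity excluded.

    Each iteration is a single shuffle of the full vector, reused across
    all searchlight centers of that iteration; class counts are preserved
    by construction.  Errors if more permutations are requested than
    distinct non-identity arrangements exist (only relevant for tiny n).
    """
    labels = np.asarray(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = labels.shape[0]
    n_pos = int((labels == labels.max()).sum()) if n else 0
    n_distinct = comb(n, n_pos) - 1  # non-identity arrangements
    if n_perm > n_distinct:
        raise ValueError(
            f"{n_perm} permutations requested but only {n_distinct} distinct "
            "non-identity label arrangements exist"
        )
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, n), dtype=labels.dtype)
    for i in range(n_perm):
        while True:
            perm = rng.permutation(labels)
            if not np.array_equal(perm, labels):
                break
        out[i] = perm
    return out


def build_null_svc(
    stack: SubjectVolumeStack,
    labels,
    mask: MaskVolume,
    spec: SearchlightSpec,
    solver: SolverConfig,
    perm_config: PermutationConfig,
) -> PermutationNull:
    """Chance accuracy distribution: full searchlight LOOCV per permutation.

    Every permutation step re-runs the entire leave-one-subject-out
    searchlight under one global relabelling; the center-voxel accuracy
    samples form the per-voxel chance histograms.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if not np.all(np.isin(labels, (-1.0, 1.0))):
        raise ValueError("labels must be +1/-1")
    if not mask.grid.compatible(stack.grid):
        raise ValueError("mask grid does not match volume stack grid")
    perms = generate_label_permutations(labels, perm_config.n_perm, perm_config.seed)
    centers, neigh_flat, neigh_ptr = neighbor_table(mask, spec)
    n = stack.n_subjects
    data_flat = stack.flat()
    n_iter = solver.n_iter(n - 1)
    samples = np.empty((perm_config.n_perm, centers.shape[0]), dtype=np.float32)
    for p in range(perm_config.n_perm):
        ylab = perms[p]
        scores = _kernels.searchlight_svc_scores(
            data_flat, ylab, neigh_flat, neigh_ptr,
            solver.C, n_iter, np.uint64(perm_config.seed), solver.use_bias,
            np.uint64(p + 1),
        )
        preds = np.where(scores >= 0.0, 1.0, -1.0)
        ref = ylab if perm_config.score_against_permuted else labels
        samples[p] = 100.0 * (preds == ref[None, :]).mean(axis=1)
        samples[p][~np.isfinite(scores).all(axis=1)] = np.nan
    return PermutationNull(samples, centers, perm_config.seed, perm_config.scheme)


def empirical_pvalue(observed, null_samples) -> np.ndarray | float:
    """Right-tailed plus-one estimator p = (1 + #{null >= obs}) / (P + 1).

    ``observed`` may be a scalar with a 1-D null, or a length-V vector with
    an (P, V) per-voxel null.
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise ValueError("empty null distribution")
    obs = np.asarray(observed, dtype=float)
    if not np.isfinite(obs).all():
        raise ValueError("non-finite observed statistic")
    if null_samples.ndim == 1 and obs.ndim == 0:
        n = null_samples.shape[0]
        return float((1 + (null_samples >= obs).sum()) / (n + 1))
    if null_samples.ndim == 2 and obs.shape == (null_samples.shape[1],):
        n = null_samples.shape[0]
        return (1 + (null_samples >= obs[None, :]).sum(axis=0)) / (n + 1)
    raise ValueError("observed/null shapes incompatible")


def pvalue_map(
    observed_map: StatMap, null: PermutationNull, mask: MaskVolume
) -> StatMap:
    """Per-voxel empirical p-values on the grid (NaN outside the mask)."""
    cidx = tuple(null.centers.T)
    obs = observed_map.data[cidx]
    keep = np.isfinite(obs) & np.isfinite(null.samples).all(axis=0)
    p = np.full(obs.shape, np.nan)
    if keep.any():
        p[keep] = empirical_pvalue(obs[keep], null.samples[:, keep])
    out = np.full(observed_map.grid.dims, np.nan)
    out[cidx] = p
    return StatMap(observed_map.grid, out, name=f"{observed_map.name}_p")


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level q.

    Returns ``(reject, threshold)`` where ``threshold`` is the largest
    p-value declared significant (0.0 when nothing is rejected).  NaN
    entries are never rejected and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    finite = np.isfinite(p)
    pf = p[finite]
    if pf.size and ((pf < 0).any() or (pf > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    m = pf.size
    if m == 0:
        return reject, 0.0
    order = np.sort(pf)
    crit = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(order <= crit)
    if passing.size == 0:
        return reject, 0.0
    thresh = order[passing[-1]]
    reject[finite] = p[finite] <= thresh
    return reject, float(thresh)


def cluster_filter(
    binary_map: np.ndarray,
    min_size: int = 30,
    connectivity: int = 18,
    stat_map: StatMap | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Connected-component extent filtering of a thresholded map.

    Components smaller than ``min_size`` voxels are removed (the boundary
    is inclusive: a component of exactly ``min_size`` survives).  Returns
    the cluster table (id, size, peak voxel and mm coordinates, peak
    statistic from ``stat_map`` if given) and the filtered binary map.
    """
    binary_map = np.asarray(binary_map)
    uniq = np.unique(binary_map[np.isfinite(binary_map.astype(float))])
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("cluster_filter expects a binary map")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    lab, n_lab = ndimage.label(binary_map.astype(bool), structure=_STRUCTURES[connectivity])
    rows = []
    keep = np.zeros(binary_map.shape, dtype=bool)
    cid = 0
    for k in range(1, n_lab + 1):
        member = lab == k
        size = int(member.sum())
        if size < min_size:
            continue
        cid += 1
        keep |= member
        if stat_map is not None:
            vals = np.where(member, stat_map.data, -np.inf)
            flat = int(np.nanargmax(vals))
            peak = np.unravel_index(flat, vals.shape)
            peak_stat = float(stat_map.data[peak])
            world = stat_map.grid.voxel_to_world(peak)
        else:
            idx = np.argwhere(member)
            peak = tuple(idx[0])
            peak_stat = np.nan
            world = (np.nan, np.nan, np.nan)
        rows.append(
            {
                "cluster_id": cid,
                "size_voxels": size,
                "peak_i": int(peak[0]),
                "peak_j": int(peak[1]),
                "peak_k": int(peak[2]),
                "peak_x_mm": float(world[0]),
                "peak_y_mm": float(world[1]),
                "peak_z_mm": float(world[2]),
                "peak_stat": peak_stat,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size_voxels", "peak_i", "peak_j", "peak_k",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_stat",
        ],
    )
    return table, keep
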