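"""Cohort summary statistics and cluster-peak report tables.

Reproduces the two report formats of the analysis: a demographics table
(per-group and pooled mean/SD for numeric covariates with pooled-variance
t-tests, per-group counts with Pearson chi-square for categorical ones),
and the peak table for significant clusters (peak mm coordinates,
accuracy/sensitivity/specificity, the minimum and mean accuracy within a
6 mm sphere around the peak, and the chance minimum/mean/maximum at the
peak from the permutation null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PermutationNull
from .univariate import two_sample_t
from .volumes import MaskVolume, StatMap, sphere_offsets

__all__ = [
    "pearson_chi_square",
    "CohortSummary",
    "cohort_summary",
    "peak_table",
]


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction.

    Returns (chi2, df=1, p).  Errors on non-integer/negative counts or a
    zero margin (expected counts undefined).
    """
    from scipy.stats import chi2 as chi2_dist

    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    if (obs < 0).any() or not np.all(obs == np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, 1, float(chi2_dist.sf(chi2, df=1))


@dataclass
class CohortSummary:
    """Per-group + pooled covariate summaries with between-group tests."""

    numeric: pd.DataFrame  # rows: field; columns: group means/SDs, pooled, t, p
    categorical: pd.DataFrame  # rows: field; per-group counts, chi2, p
    n_per_group: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(self.n_per_group.values())


def cohort_summary(
    records: pd.DataFrame,
    numeric_fields=(),
    categorical_fields=(),
) -> CohortSummary:
    """Demographics-table summary of a cohort record table.

    ``records`` needs a ``group`` column (patient/control).  Numeric fields
    get per-group and pooled mean (SD) plus a pooled-variance two-sample t;
    binary categorical fields get per-group counts plus Pearson chi-square.
    For equal group sizes the pooled mean equals the unweighted mean of the
    group means.
    """
    if "group" not in records.columns:
        raise ValueError("records missing required column 'group'")
    groups = ["control", "patient"]
    sub = {g: records[records["group"] == g] for g in groups}
    for g in groups:
        if len(sub[g]) < 1:
            raise ValueError(f"no records for group {g!r}")
    num_rows = []
    for f in numeric_fields:
        if f not in records.columns:
            raise ValueError(f"missing numeric field {f!r}")
        a = sub["control"][f].dropna().to_numpy(dtype=float)
        b = sub["patient"][f].dropna().to_numpy(dtype=float)
        pooled = np.concatenate([a, b])
        row = {
            "field": f,
            "control_mean": a.mean(),
            "control_sd": a.std(ddof=1) if a.size > 1 else 0.0,
            "patient_mean": b.mean(),
            "patient_sd": b.std(ddof=1) if b.size > 1 else 0.0,
            "pooled_mean": pooled.mean(),
            "pooled_sd": pooled.std(ddof=1) if pooled.size > 1 else 0.0,
        }
        try:
            t, df, p = two_sample_t(a, b)
            row.update(t=round(t, 2), df=df, p=p)
        except ValueError:
            row.update(t=np.nan, df=a.size + b.size - 2, p=np.nan)
        num_rows.append(row)
    cat_rows = []
    for f in categorical_fields:
        if f not in records.columns:
            raise ValueError(f"missing categorical field {f!r}")
        levels = sorted(records[f].dropna().unique().tolist())
        counts = {
            g: [int((sub[g][f] == lv).sum()) for lv in levels] for g in groups
        }
        row = {
            "field": f,
            "levels": levels,
            "control_counts": counts["control"],
            "patient_counts": counts["patient"],
        }
        if len(levels) == 2:
            tab = np.array([counts["control"], counts["patient"]])
            try:
                chi2, df, p = pearson_chi_square(tab)
                row.update(chi2=round(chi2, 2), df=df, p=p)
            except ValueError:
                row.update(chi2=np.nan, df=1, p=np.nan)
        else:
            row.update(chi2=np.nan, df=np.nan, p=np.nan)
        cat_rows.append(row)
    return CohortSummary(
        numeric=pd.DataFrame(num_rows),
        categorical=pd.DataFrame(cat_rows),
        n_per_group={g: len(sub[g]) for g in groups},
    )


def peak_table(
    stat_map: StatMap,
    sig_mask: np.ndarray,
    cluster_table: pd.DataFrame,
    companion_maps: dict[str, StatMap],
    null: PermutationNull | None = None,
    neighborhood_radius_mm: float = 6.0,
) -> pd.DataFrame:
    """One report row per significant cluster.

    Columns: peak mm coordinates, the primary statistic (accuracy) at the
    peak, companion statistics (sensitivity/specificity) there, the
    minimum and mean of the primary map within the ``neighborhood_radius_mm``
    sphere around the peak (radius converted to voxels, inclusive
    boundary, clipped at the grid edge and restricted to map support), and
    the chance min/mean/max at the peak from the permutation null.
    Accuracies are reported to one decimal.
    """
    grid = stat_map.grid
    for name, m in companion_maps.items():
        if not m.grid.compatible(grid):
            raise ValueError(f"companion map {name!r} on a different grid")
    radius_vox = neighborhood_radius_mm / grid.voxel_size_mm
    offs = sphere_offsets(2 * radius_vox)
    dims = np.asarray(grid.dims)
    rows = []
    for _, cl in cluster_table.iterrows():
        peak = np.array([cl["peak_i"], cl["peak_j"], cl["peak_k"]], dtype=int)
        peak_val = stat_map.data[tuple(peak)]
        if not np.isfinite(peak_val):
            raise ValueError(f"cluster peak {tuple(peak)} outside stat map support")
        row = {
            "cluster_id": int(cl["cluster_id"]),
            "size_voxels": int(cl["size_voxels"]),
            "x_mm": round(float(cl["peak_x_mm"]), 1),
            "y_mm": round(float(cl["peak_y_mm"]), 1),
            "z_mm": round(float(cl["peak_z_mm"]), 1),
            stat_map.name: round(float(peak_val), 1),
        }
        for name, m in companion_maps.items():
            v = m.data[tuple(peak)]
            if not np.isfinite(v):
                raise ValueError(
                    f"cluster peak {tuple(peak)} outside companion map {name!r} support"
                )
            row[name] = round(float(v), 1)
        pts = peak[None, :] + offs
        inb = ((pts >= 0) & (pts < dims)).all(axis=1)
        vals = stat_map.data[tuple(pts[inb].T)]
        vals = vals[np.isfinite(vals)]
        row["neigh_min"] = round(float(vals.min()), 1)
        row["neigh_mean"] = round(float(vals.mean()), 1)
        if null is not None:
            chance = null.at_center(peak)
            row["chance_min"] = round(float(np.nanmin(chance)), 1)
            row["chance_mean"] = round(float(np.nanmean(chance)), 1)
            row["chance_max"] = round(float(np.nanmax(chance)), 1)
        rows.append(row)
    return pd.DataFrame(rows)
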