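"""Univariate baselines: voxelwise t-maps, ROC maximum accuracy, McNemar.

The univariate counterpart of the searchlight decoder treats each voxel on
its own: a pooled-variance two-sample t contrasts the group means
(controls minus patients), and the ROC maximum-accuracy map records, per
voxel, the best achievable in-sample classification rate over every
threshold and both decision directions.  The in-sample (non-cross-validated)
definition is deliberate — it upper-bounds what a single voxel can do, which
is the comparison the searchlight maps are benchmarked against.  McNemar's
test compares the paired per-subject correctness of two classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volumes import MaskVolume, StatMap, SubjectVolumeStack

__all__ = [
    "RocResult",
    "McNemarResult",
    "two_sample_t",
    "two_sample_t_from_stats",
    "voxelwise_t_map",
    "roc_max_accuracy",
    "run_roc_accuracy_map",
    "mcnemar_test",
]


def two_sample_t(group_a, group_b) -> tuple[float, int, float]:
    """Pooled-variance Student t with two-sided p; returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), int(df), float(res.pvalue)


def two_sample_t_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, int, float]:
    """Pooled-variance t from group summary statistics (printed-table use)."""
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True)
    return float(res.statistic), int(n_a + n_b - 2), float(res.pvalue)


def voxelwise_t_map(
    stack: SubjectVolumeStack, labels, mask: MaskVolume
) -> StatMap:
    """Two-sample t at every mask voxel, contrast controls minus patients.

    A positive t marks voxels where controls exceed patients (the reported
    direction of the group difference).  Voxels with zero pooled variance
    get NaN with a single warning; if every voxel is degenerate an error is
    raised.
    """
    labels = np.asarray(labels)
    if not mask.grid.compatible(stack.grid):
        raise ValueError("mask grid does not match stack grid")
    pos = labels == 1
    neg = labels == -1
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    vals = stack.flat()[:, mask.data.reshape(-1)]
    a = vals[neg]  # controls
    b = vals[pos]  # patients
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    zero = sp2 <= 0
    if zero.all():
        raise ValueError("zero pooled variance at every mask voxel")
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} mask voxels have zero pooled variance; t set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[zero] = np.nan
    out = np.full(mask.grid.dims, np.nan)
    out[mask.data] = t
    return StatMap(mask.grid, out, name="t_controls_minus_patients")


@dataclass(frozen=True)
class RocResult:
    """Best in-sample accuracy over all thresholds and both directions."""

    max_accuracy: float  # percent
    threshold: float  # contrast units
    direction: int  # +1: patients above threshold; -1: patients below

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


def roc_max_accuracy(values, labels) -> RocResult:
    """Scan every cut-point between sorted distinct values, both directions.

    Thresholds sit at midpoints between consecutive distinct values plus
    sentinels beyond the extremes (so the majority-class rule is always
    available, giving >= 50% for balanced groups).  Returns the maximum
    in-sample accuracy, the threshold achieving it and the direction.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be aligned 1-D arrays")
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be +1/-1")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    u = np.unique(v)
    thr = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    n = v.size
    best = (-1.0, 0.0, 1)
    for t in thr:
        above = v > t
        # direction +1: predict patient above threshold
        acc_hi = ((above & (y == 1)) | (~above & (y == -1))).sum() / n
        acc_lo = 1.0 - acc_hi  # flipping direction flips every prediction
        if acc_hi > best[0]:
            best = (acc_hi, t, 1)
        if acc_lo > best[0]:
            best = (acc_lo, t, -1)
    return RocResult(max_accuracy=100.0 * best[0], threshold=float(best[1]), direction=best[2])


def _max_accuracy_fraction(values: np.ndarray, labels: np.ndarray) -> float:
    """Fast scan equivalent of :func:`roc_max_accuracy` (fraction, not %).

    Sweeps the sorted values once; at each boundary between distinct
    values the accuracy of the "patients above threshold" rule updates by
    cumulative class counts, and the opposite direction is its complement.
    """
    order = np.argsort(values, kind="stable")
    vs = values[order]
    ys = labels[order]
    n = values.size
    n_pos = int((labels == 1).sum())
    cum_pos = np.concatenate([[0], np.cumsum(ys == 1)])
    cum_neg = np.concatenate([[0], np.cumsum(ys == -1)])
    valid = np.ones(n + 1, dtype=bool)
    valid[1:n] = vs[1:] != vs[:-1]
    acc_hi = (n_pos - cum_pos + cum_neg) / n
    acc = np.maximum(acc_hi, 1.0 - acc_hi)[valid]
    return float(acc.max())


def run_roc_accuracy_map(
    stack: SubjectVolumeStack, labels, mask: MaskVolume
) -> StatMap:
    """Per-voxel ROC maximum accuracy (%), mapped over the mask."""
    labels = np.asarray(labels)
    if not mask.grid.compatible(stack.grid):
        raise ValueError("mask grid does not match stack grid")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    vals = stack.flat()[:, mask.data.reshape(-1)]
    out = np.full(mask.grid.dims, np.nan)
    accs = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        accs[j] = 100.0 * _max_accuracy_fraction(vals[:, j], labels)
    out[mask.data] = accs
    return StatMap(mask.grid, out, name="roc_accuracy")


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p: float
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    degenerate: bool = False


def mcnemar_test(correct_a, correct_b, continuity: bool = True) -> McNemarResult:
    """McNemar's test on paired per-subject correctness flags.

    ``b`` counts subjects A got right and B wrong, ``c`` the reverse; the
    statistic is (|b-c|-1)^2/(b+c) with continuity correction (default) or
    (b-c)^2/(b+c) without, referred to chi-square with 1 df.  When no
    discordant pairs exist the statistic is undefined and a degenerate
    result is returned.
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape or a.ndim != 1:
        raise ValueError("correctness vectors must be aligned 1-D arrays")
    b = int((a & ~bb).sum())
    c = int((~a & bb).sum())
    if b + c == 0:
        return McNemarResult(np.nan, np.nan, b, c, degenerate=True)
    if continuity:
        stat = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(float(stat), p, b, c)
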