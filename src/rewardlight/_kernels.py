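"""Compiled numerical kernels: Pegasos solvers, LOOCV and searchlight loops.

The stochastic sub-gradient SVM solver is the innermost loop of every map
in the package (each permutation step re-runs a full leave-one-subject-out
searchlight), so the solver, the fold loop and the voxel loop live here as
numba-compiled functions.  Randomness comes from an in-kernel splitmix64
generator seeded per (permutation, voxel, fold), which makes every map
bit-reproducible and independent of voxel execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# splitmix64 constants
_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _mix64(z):
    z = np.uint64(z) * np.uint64(0xFF51AFD7ED558CCD)
    z ^= z >> np.uint64(33)
    z = z * np.uint64(0xC4CEB9FE1A85EC53)
    z ^= z >> np.uint64(33)
    return z


@njit(cache=True, inline="always")
def _next64(state):
    """Advance splitmix64; returns (new_state, output)."""
    state = state + _GAMMA
    z = state
    z ^= z >> np.uint64(30)
    z = z * _M1
    z ^= z >> np.uint64(27)
    z = z * _M2
    z ^= z >> np.uint64(31)
    return state, z


@njit(cache=True)
def derive_seed(base, a, b):
    """Deterministic child seed from (base, a, b); order-independent use."""
    return _mix64(np.uint64(base) ^ _mix64(np.uint64(a) + np.uint64(0x1F123BB5) * np.uint64(b + 1)))


@njit(cache=True, fastmath=True)
def pegasos_svc(X, y, lam, n_iter, seed, project, avg_last_half):
    """Pegasos stochastic sub-gradient descent on the hinge-loss objective.

    Minimises f(w) = lam/2 ||w||^2 + mean_i max(0, 1 - y_i <x_i, w>), one
    uniformly sampled example per iteration, step size 1/(lam*t).  Returns
    the average of the iterates over the last half of the run (or the final
    iterate when ``avg_last_half`` is false).  ``project`` enables the
    optional projection onto the ball of radius 1/sqrt(lam).
    """
    n, d = X.shape
    w = np.zeros(d)
    wsum = np.zeros(d)
    state = _mix64(np.uint64(seed) ^ np.uint64(0xD6E8FEB86659FD93))
    t_avg_start = n_iter // 2 if avg_last_half else n_iter - 1
    radius2 = 1.0 / lam if lam > 0 else np.inf
    n_avg = 0
    for t in range(1, n_iter + 1):
        state, z = _next64(state)
        i = np.int64(z % np.uint64(n))
        margin = 0.0
        for k in range(d):
            margin += w[k] * X[i, k]
        margin *= y[i]
        eta = 1.0 / (lam * t)
        scale = 1.0 - 1.0 / t
        if margin < 1.0:
            c = eta * y[i]
            for k in range(d):
                w[k] = scale * w[k] + c * X[i, k]
        else:
            for k in range(d):
                w[k] = scale * w[k]
        if project:
            nrm2 = 0.0
            for k in range(d):
                nrm2 += w[k] * w[k]
            if nrm2 > radius2:
                shrink = np.sqrt(radius2 / nrm2)
                for k in range(d):
                    w[k] *= shrink
        if t > t_avg_start:
            n_avg += 1
            for k in range(d):
                wsum[k] += w[k]
    for k in range(d):
        wsum[k] /= n_avg
    return wsum


@njit(cache=True, fastmath=True)
def pegasos_svr(X, y, lam, eps_tube, n_iter, seed, avg_last_half):
    """Stochastic sub-gradient descent on the epsilon-insensitive objective.

    Minimises f(w) = lam/2 ||w||^2 + mean_i max(0, |<x_i, w> - y_i| - eps).
    Mirrors :func:`pegasos_svc` with the hinge replaced by the eps-tube loss.
    """
    n, d = X.shape
    w = np.zeros(d)
    wsum = np.zeros(d)
    state = _mix64(np.uint64(seed) ^ np.uint64(0xA2F9B1D1D5C6E2A7))
    t_avg_start = n_iter // 2 if avg_last_half else n_iter - 1
    n_avg = 0
    for t in range(1, n_iter + 1):
        state, z = _next64(state)
        i = np.int64(z % np.uint64(n))
        pred = 0.0
        for k in range(d):
            pred += w[k] * X[i, k]
        r = pred - y[i]
        eta = 1.0 / (lam * t)
        scale = 1.0 - 1.0 / t
        if r > eps_tube:
            for k in range(d):
                w[k] = scale * w[k] - eta * X[i, k]
        elif r < -eps_tube:
            for k in range(d):
                w[k] = scale * w[k] + eta * X[i, k]
        else:
            for k in range(d):
                w[k] = scale * w[k]
        if t > t_avg_start:
            n_avg += 1
            for k in range(d):
                wsum[k] += w[k]
    for k in range(d):
        wsum[k] /= n_avg
    return wsum


@njit(cache=True, fastmath=True)
def loocv_svc_scores(X, y, C, n_iter, seed, use_bias):
    """Leave-one-subject-out decision values for a single feature block.

    For each fold j the model is trained on the other n-1 subjects with
    lam = 1/((n-1) C) and scored on subject j.  Returns the per-subject
    decision value <w, x_j> (+ regularised bias if ``use_bias``).
    """
    n, d0 = X.shape
    d = d0 + 1 if use_bias else d0
    Xb = np.empty((n, d))
    for i in range(n):
        for k in range(d0):
            Xb[i, k] = X[i, k]
        if use_bias:
            Xb[i, d0] = 1.0
    scores = np.empty(n)
    lam = 1.0 / ((n - 1) * C)
    Xtr = np.empty((n - 1, d))
    ytr = np.empty(n - 1)
    for j in range(n):
        r = 0
        for i in range(n):
            if i == j:
                continue
            for k in range(d):
                Xtr[r, k] = Xb[i, k]
            ytr[r] = y[i]
            r += 1
        w = pegasos_svc(Xtr, ytr, lam, n_iter, derive_seed(seed, j, 0), False, True)
        s = 0.0
        for k in range(d):
            s += w[k] * Xb[j, k]
        scores[j] = s
    return scores


@njit(cache=True, fastmath=True)
def loocv_svr_predict(X, y, C, eps_tube, n_iter, seed, use_bias):
    """Leave-one-out epsilon-SVR predictions for a single feature block."""
    n, d0 = X.shape
    d = d0 + 1 if use_bias else d0
    Xb = np.empty((n, d))
    for i in range(n):
        for k in range(d0):
            Xb[i, k] = X[i, k]
        if use_bias:
            Xb[i, d0] = 1.0
    preds = np.empty(n)
    lam = 1.0 / ((n - 1) * C)
    Xtr = np.empty((n - 1, d))
    ytr = np.empty(n - 1)
    for j in range(n):
        r = 0
        ym = 0.0
        for i in range(n):
            if i == j:
                continue
            for k in range(d):
                Xtr[r, k] = Xb[i, k]
            ytr[r] = y[i]
            ym += y[i]
            r += 1
        # unregularised intercept: fit residuals around the fold mean
        if use_bias:
            ym /= n - 1
            for i in range(n - 1):
                ytr[i] -= ym
        else:
            ym = 0.0
        w = pegasos_svr(Xtr, ytr, lam, eps_tube, n_iter, derive_seed(seed, j, 1), True)
        s = ym
        for k in range(d):
            s += w[k] * Xb[j, k]
        preds[j] = s
    return preds


@njit(cache=True, fastmath=True)
def searchlight_svc_scores(
    data_flat, y, neigh_flat, neigh_ptr, C, n_iter, base_seed, use_bias, perm_index
):
    """LOOCV decision values at every searchlight center.

    ``data_flat`` is (n_subjects, n_grid_voxels); the features of center c
    are the columns ``neigh_flat[neigh_ptr[c]:neigh_ptr[c+1]]``.  Centers
    whose sphere contains a non-finite value yield NaN scores.  Seeds are
    derived from (base_seed, perm_index, center), so results do not depend
    on the order in which centers are processed.
    """
    n = data_flat.shape[0]
    n_centers = neigh_ptr.shape[0] - 1
    out = np.full((n_centers, n), np.nan)
    for c in range(n_centers):
        lo = neigh_ptr[c]
        hi = neigh_ptr[c + 1]
        d0 = hi - lo
        X = np.empty((n, d0))
        ok = True
        for i in range(n):
            for k in range(d0):
                v = data_flat[i, neigh_flat[lo + k]]
                if not np.isfinite(v):
                    ok = False
                X[i, k] = v
        if not ok:
            continue
        seed = derive_seed(base_seed, perm_index, c)
        sc = loocv_svc_scores(X, y, C, n_iter, seed, use_bias)
        for i in range(n):
            out[c, i] = sc[i]
    return out


@njit(cache=True, fastmath=True)
def loocv_svr_predict_permuted(X, scores, perm, C, eps_tube, n_iter, seed, use_bias):
    """Null-model LOOCV SVR: training scores reassigned within each fold.

    ``perm`` is one global permutation of patient indices.  In fold j the
    training patient i receives score ``scores[perm[i]]``, patched so that
    the held-out patient's own score never enters training: if perm maps
    some trainee to j, that trainee receives ``scores[perm[j]]`` instead.
    Each fold therefore trains on exactly the training patients' scores,
    randomly reassigned, while predictions are evaluated against the true
    scores downstream.
    """
    n, d0 = X.shape
    d = d0 + 1 if use_bias else d0
    Xb = np.empty((n, d))
    for i in range(n):
        for k in range(d0):
            Xb[i, k] = X[i, k]
        if use_bias:
            Xb[i, d0] = 1.0
    preds = np.empty(n)
    lam = 1.0 / ((n - 1) * C)
    Xtr = np.empty((n - 1, d))
    ytr = np.empty(n - 1)
    for j in range(n):
        r = 0
        ym = 0.0
        for i in range(n):
            if i == j:
                continue
            for k in range(d):
                Xtr[r, k] = Xb[i, k]
            v = perm[i]
            if v == j:
                v = perm[j]
            ytr[r] = scores[v]
            ym += scores[v]
            r += 1
        if use_bias:
            ym /= n - 1
            for i in range(n - 1):
                ytr[i] -= ym
        else:
            ym = 0.0
        w = pegasos_svr(Xtr, ytr, lam, eps_tube, n_iter, derive_seed(seed, j, 1), True)
        s = ym
        for k in range(d):
            s += w[k] * Xb[j, k]
        preds[j] = s
    return preds


@njit(cache=True, fastmath=True)
def searchlight_svr_null_predictions(
    data_flat, scores, perm, neigh_flat, neigh_ptr, C, eps_tube, n_iter,
    base_seed, use_bias, perm_index
):
    """Null-SVR searchlight: fold-patched score reassignment at every center."""
    n = data_flat.shape[0]
    n_centers = neigh_ptr.shape[0] - 1
    out = np.full((n_centers, n), np.nan)
    for c in range(n_centers):
        lo = neigh_ptr[c]
        hi = neigh_ptr[c + 1]
        d0 = hi - lo
        X = np.empty((n, d0))
        ok = True
        for i in range(n):
            for k in range(d0):
                v = data_flat[i, neigh_flat[lo + k]]
                if not np.isfinite(v):
                    ok = False
                X[i, k] = v
        if not ok:
            continue
        seed = derive_seed(base_seed, perm_index, c)
        pr = loocv_svr_predict_permuted(X, scores, perm, C, eps_tube, n_iter, seed, use_bias)
        for i in range(n):
            out[c, i] = pr[i]
    return out


@njit(cache=True, fastmath=True)
def searchlight_svr_predictions(
    data_flat, y, neigh_flat, neigh_ptr, C, eps_tube, n_iter, base_seed, use_bias, perm_index
):
    """LOOCV SVR predictions at every searchlight center (see SVC variant)."""
    n = data_flat.shape[0]
    n_centers = neigh_ptr.shape[0] - 1
    out = np.full((n_centers, n), np.nan)
    for c in range(n_centers):
        lo = neigh_ptr[c]
        hi = neigh_ptr[c + 1]
        d0 = hi - lo
        X = np.empty((n, d0))
        ok = True
        for i in range(n):
            for k in range(d0):
                v = data_flat[i, neigh_flat[lo + k]]
                if not np.isfinite(v):
                    ok = False
                X[i, k] = v
        if not ok:
            continue
        seed = derive_seed(base_seed, perm_index, c)
        pr = loocv_svr_predict(X, y, C, eps_tube, n_iter, seed, use_bias)
        for i in range(n):
            out[c, i] = pr[i]
    return out
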