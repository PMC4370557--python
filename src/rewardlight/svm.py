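"""Primal linear SVM classification and regression via Pegasos.

The classifier minimises the regularised hinge-loss objective

    f(w) = lam/2 ||w||^2 + (1/n) sum_i max(0, 1 - y_i <x_i, w>),

with lam = 1/(nC), by stochastic sub-gradient descent: at iteration t a
single uniformly drawn training example estimates a sub-gradient and a
step of size 1/(lam*t) is taken.  The regression variant replaces the
hinge with the epsilon-insensitive loss.  The reported solution is the
average of the iterates over the last half of the run, which stabilises
the stochastic trajectory; for a long enough run it is an eps-accurate
solution f(w_hat) <= f(w*) + eps.

The intercept is handled by appending a constant-1 feature, so the bias is
regularised together with w.  An unbiased variant (``use_bias=False``)
reproduces the plain primal formulation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional
import warnings

import numpy as np

from . import _kernels

__all__ = [
    "SolverConfig",
    "LinearModel",
    "svc_objective",
    "svr_objective",
    "train_svc_pegasos",
    "train_svr",
    "predict_svc",
    "predict_svr",
]

MAX_ITER_CAP = 100_000


@dataclass(frozen=True)
class SolverConfig:
    """Solver settings shared by the SVC and SVR paths.

    ``C`` is the per-example cost; the regularisation used internally is
    lam = 1/(nC), so both parameterisations describe the same objective.
    ``max_iter`` defaults to ceil(20 / (lam * epsilon_solution)) capped at
    100,000; searchlight runs typically pass an explicit, smaller value.
    """

    C: float = 1.0
    epsilon_solution: float = 1e-3
    epsilon_tube: float = 0.1
    max_iter: Optional[int] = None
    seed: int = 0
    use_bias: bool = True
    project: bool = False
    average_last_half: bool = True

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon_solution <= 0:
            raise ValueError("epsilon_solution must be positive")
        if self.epsilon_tube < 0:
            raise ValueError("epsilon_tube must be non-negative")
        if self.max_iter is not None and self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def lam(self, n: int) -> float:
        """Regularisation parameter lam = 1/(nC) for n training examples."""
        return 1.0 / (n * self.C)

    def n_iter(self, n: int) -> int:
        if self.max_iter is not None:
            return int(self.max_iter)
        return int(min(np.ceil(20.0 / (self.lam(n) * self.epsilon_solution)), MAX_ITER_CAP))

    def with_(self, **kw) -> "SolverConfig":
        return replace(self, **kw)


@dataclass
class LinearModel:
    """A trained linear model over a searchlight's voxel features."""

    w: np.ndarray
    bias: float
    objective_value: float
    n_iter: int
    seed: int
    kind: str = "svc"  # or "svr"

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.w.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model ({self.w.shape[0]})"
            )
        return X @ self.w + self.bias


def _validate_xy(X, y, classification: bool):
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (n, d) array")
    if y.shape != (X.shape[0],):
        raise ValueError("labels/targets must align with feature rows")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite entries in training data")
    if classification:
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("classification labels must be +1/-1")
        if np.unique(y).size < 2:
            raise ValueError("training set contains a single class (degenerate margin)")
    return X, y


def _hinge_mean(w, X, y):
    m = 1.0 - y * (X @ w)
    return float(np.maximum(m, 0.0).mean())


def svc_objective(w: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Regularised hinge objective lam/2 ||w||^2 + mean hinge loss."""
    w = np.asarray(w, dtype=float)
    if not np.isfinite(w).all():
        raise ValueError("non-finite weight vector")
    X, y = _validate_xy(X, y, classification=True)
    if w.shape != (X.shape[1],):
        raise ValueError("weight dimension does not match features")
    return 0.5 * lam * float(w @ w) + _hinge_mean(w, X, y)


def svr_objective(
    w: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float, eps_tube: float
) -> float:
    """Regularised epsilon-insensitive objective."""
    w = np.asarray(w, dtype=float)
    if not np.isfinite(w).all():
        raise ValueError("non-finite weight vector")
    X, y = _validate_xy(X, y, classification=False)
    loss = np.maximum(np.abs(X @ w - y) - eps_tube, 0.0).mean()
    return 0.5 * lam * float(w @ w) + float(loss)


def _augment(X, use_bias):
    if not use_bias:
        return X
    return np.ascontiguousarray(np.hstack([X, np.ones((X.shape[0], 1))]))


def train_svc_pegasos(X: np.ndarray, y: np.ndarray, config: SolverConfig) -> LinearModel:
    """Train the linear SVC by Pegasos; deterministic given ``config.seed``."""
    X, y = _validate_xy(X, y, classification=True)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two training examples")
    lam = config.lam(n)
    n_iter = config.n_iter(n)
    Xb = _augment(X, config.use_bias)
    w_full = _kernels.pegasos_svc(
        Xb, y, lam, n_iter, np.uint64(config.seed), config.project, config.average_last_half
    )
    w, b = (w_full[:-1], float(w_full[-1])) if config.use_bias else (w_full, 0.0)
    obj = 0.5 * lam * float(w_full @ w_full) + _hinge_mean(w_full, Xb, y)
    return LinearModel(w=np.asarray(w), bias=b, objective_value=obj,
                       n_iter=n_iter, seed=config.seed, kind="svc")


def predict_svc(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels sign(<w, x> + bias); a tie at exactly 0 maps to +1."""
    scores = model.decision_values(X)
    return np.where(scores >= 0.0, 1, -1)


def train_svr(X: np.ndarray, y: np.ndarray, config: SolverConfig) -> LinearModel:
    """Train linear epsilon-insensitive SVR by the Pegasos-style solver."""
    X, y = _validate_xy(X, y, classification=False)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two training examples")
    if not config.use_bias and np.ptp(y) > 0:
        spans = np.ptp(X, axis=0)
        if np.all(spans == 0):
            warnings.warn(
                "constant features with use_bias off and non-constant targets: "
                "the epsilon-tube loss is irreducible",
                RuntimeWarning,
                stacklevel=2,
            )
    lam = config.lam(n)
    n_iter = config.n_iter(n)
    Xb = _augment(X, config.use_bias)
    # With use_bias the intercept is unregularised: the target mean is
    # absorbed before fitting (mirroring the standard SVR intercept) and a
    # regularised residual-bias feature mops up what remains.
    y_mean = float(y.mean()) if config.use_bias else 0.0
    yc = y - y_mean
    w_full = _kernels.pegasos_svr(
        Xb, yc, lam, config.epsilon_tube, n_iter, np.uint64(config.seed),
        config.average_last_half,
    )
    w, b = (w_full[:-1], y_mean + float(w_full[-1])) if config.use_bias else (w_full, 0.0)
    loss = np.maximum(np.abs(Xb @ w_full - yc) - config.epsilon_tube, 0.0).mean()
    obj = 0.5 * lam * float(w_full @ w_full) + float(loss)
    return LinearModel(w=np.asarray(w), bias=b, objective_value=obj,
                       n_iter=n_iter, seed=config.seed, kind="svr")


def predict_svr(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """SVR predictions <w, x> + bias."""
    return model.decision_values(X)
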