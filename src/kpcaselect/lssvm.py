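"""Least-squares SVM binary classifier in the dual.

The LS-SVM replaces the hinge loss by squared error, so training reduces to
one bordered linear system

    [ 0   y'        ] [ b    ]   [ 0   ]
    [ y   Omega+I/g ] [ beta ] = [ 1_N ]

with Omega[i, j] = y_i y_j K(x_i, x_j) and regularization gamma. The latent
decision value of a point x is sum_k beta_k y_k K(x, x_k) + b; its sign is
the predicted class and the value itself ranks points for AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .kernels import KernelSpec, _pairwise

__all__ = ["LSSVMModel", "fit_lssvm", "decision_values", "predict", "tune_lssvm", "tune_gamma"]

DEFAULT_GAMMA_GRID = np.geomspace(1e-3, 1e3, 13)


@dataclass
class LSSVMModel:
    """Dual LS-SVM classifier: multipliers beta, bias b, and training data."""

    betas: np.ndarray
    b: float
    gamma: float
    spec: KernelSpec
    train_X: np.ndarray
    train_y: np.ndarray


def fit_lssvm(X, y, spec: KernelSpec, gamma: float) -> LSSVMModel:
    """Solve the bordered (N+1)-dimensional LS-SVM linear system.

    Solved by a symmetric indefinite factorization of the full bordered
    matrix; a singular system (pathological duplicates at huge gamma) falls
    back to least squares with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of samples")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    n = y.size
    K = _pairwise(X, X, spec)
    omega = (y[:, None] * y[None, :]) * K
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = omega + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], np.ones(n)])
    try:
        sol = scipy.linalg.solve(A, rhs, assume_a="sym")
        if not np.isfinite(sol).all():
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
        warnings.warn("singular LS-SVM system; solved by least squares", stacklevel=2)
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return LSSVMModel(
        betas=sol[1:], b=float(sol[0]), gamma=gamma, spec=spec, train_X=X, train_y=y
    )


def decision_values(model: LSSVMModel, points) -> np.ndarray:
    """Latent values sum_k beta_k y_k K(x, x_k) + b (sign = class)."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[1] != model.train_X.shape[1]:
        raise ValueError("feature dimension mismatch")
    K = _pairwise(P, model.train_X, model.spec)
    return K @ (model.betas * model.train_y) + model.b


def predict(model: LSSVMModel, points) -> np.ndarray:
    """Class labels in {-1, +1}; zero latent values map to +1."""
    latent = decision_values(model, points)
    return np.where(latent >= 0, 1, -1)


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Per-class round-robin fold assignment; every fold sees both classes
    whenever each class has >= folds members (else folds is reduced)."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        members = rng.permutation(np.where(y == cls)[0])
        assignment[members] = np.arange(members.size) % folds
    return [np.where(assignment == f)[0] for f in range(folds)]


def _cv_auc(X, y, spec, gamma, fold_sets) -> float:
    from .evaluation import auc

    aucs = []
    for val in fold_sets:
        train = np.setdiff1d(np.arange(y.size), val)
        model = fit_lssvm(X[train], y[train], spec, gamma)
        aucs.append(auc(decision_values(model, X[val]), y[val]))
    return float(np.mean(aucs))


def tune_lssvm(
    X,
    y,
    spec: KernelSpec,
    gamma_grid=None,
    folds: int = 10,
    seed: int = 0,
    h_grid=None,
) -> tuple[float, KernelSpec]:
    """Choose gamma (and the classifier bandwidth, for RBF) by grid CV.

    Stratified v-fold cross-validation maximizing validation AUC; ties break
    toward smaller gamma (stronger regularization) and, for RBF, smaller h.
    Deterministic given the seed. Returns ``(gamma, spec)`` with the tuned
    bandwidth substituted into the spec for RBF kernels.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    gamma_grid = DEFAULT_GAMMA_GRID if gamma_grid is None else np.asarray(gamma_grid, dtype=float)
    if gamma_grid.size == 0:
        raise ValueError("gamma grid must be nonempty")
    counts = np.bincount((y > 0).astype(int), minlength=2)
    folds = min(folds, int(counts.min()))
    if folds < 2:
        raise ValueError("each class needs at least 2 samples for CV tuning")

    for attempt in range(5):
        fold_sets = _stratified_folds(y, folds, seed + attempt)
        if all(len(np.unique(y[np.setdiff1d(np.arange(y.size), f)])) == 2 for f in fold_sets):
            break
    else:
        raise RuntimeError("could not build folds with both classes after 5 attempts")

    if spec.family == "rbf":
        if h_grid is None:
            from scipy.spatial.distance import pdist

            med = float(np.median(pdist(X)))
            med = med if med > 0 else 1.0
            h_grid = np.geomspace(0.1 * med, 10.0 * med, 7)
        specs = [replace(spec, h=float(h)) for h in np.sort(np.asarray(h_grid, dtype=float))]
    else:
        specs = [spec]

    best = (-np.inf, None, None)
    for s in specs:
        for gamma in np.sort(gamma_grid):
            score = _cv_auc(X, y, s, float(gamma), fold_sets)
            if score > best[0] + 1e-12:  # strict improvement: ties keep smaller gamma/h
                best = (score, float(gamma), s)
    return best[1], best[2]


def tune_gamma(X, y, spec: KernelSpec, grid=None, folds: int = 10, seed: int = 0) -> float:
    """Grid-CV regularization choice; see :func:`tune_lssvm`."""
    gamma, _ = tune_lssvm(X, y, spec, gamma_grid=grid, folds=folds, seed=seed)
    return gamma
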