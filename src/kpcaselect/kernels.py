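"""Kernel functions, Gram matrices, and the double-centering operator.

The centered Gram matrix Omega_c is the kernel matrix of the implicitly
mean-centered feature map,

    Omega_c[i, j] = K(x_i, x_j) - mean_r K(x_i, x_r) - mean_r K(x_j, x_r)
                    + mean_{r,s} K(x_r, x_s),

whose eigendecomposition defines kernel PCA. The same centering statistics
(per-row means and the grand mean of the training kernel matrix) extend the
centered feature map to out-of-sample points via :func:`cross_centered_kernel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "CenteredGram",
    "kernel_value",
    "gram_matrix",
    "center_gram",
    "cross_centered_kernel",
]

_FAMILIES = ("rbf", "linear", "polynomial")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and hyperparameters.

    family : "rbf" | "linear" | "polynomial"
    h : RBF bandwidth, k(a, b) = exp(-||a-b||^2 / (2 h^2)); same units as
        the (standardized) features.
    degree, offset : polynomial kernel (a.b + offset)^degree.
    """

    family: str
    h: float = 1.0
    degree: int = 3
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; use one of {_FAMILIES}")
        if self.family == "rbf" and not self.h > 0:
            raise ValueError("RBF bandwidth h must be positive")
        if self.family == "polynomial":
            if self.degree < 1:
                raise ValueError("polynomial degree must be >= 1")
            if self.offset < 0:
                raise ValueError("polynomial offset must be >= 0")


@dataclass(frozen=True)
class CenteredGram:
    """A double-centered kernel matrix together with its centering stats.

    ``row_means`` and ``grand_mean`` are retained because out-of-sample
    scoring needs the training centering, not a re-centering on test data.
    """

    omega_c: np.ndarray
    source_spec: KernelSpec | None
    row_means: np.ndarray
    grand_mean: float


def kernel_value(a, b, spec: KernelSpec) -> float:
    """Evaluate the kernel on a single pair of feature vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if spec.family == "rbf":
        diff = a - b
        return float(np.exp(-(diff @ diff) / (2.0 * spec.h**2)))
    if spec.family == "linear":
        return float(a @ b)
    return float((a @ b + spec.offset) ** spec.degree)


def _pairwise(X: np.ndarray, Y: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.family == "rbf":
        d2 = cdist(X, Y, "sqeuclidean")
        return np.exp(-d2 / (2.0 * spec.h**2))
    inner = X @ Y.T
    if spec.family == "linear":
        return inner
    return (inner + spec.offset) ** spec.degree


def gram_matrix(X, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix of the rows of X; symmetric, RBF diagonal exactly 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least two samples for a Gram matrix")
    K = _pairwise(X, X, spec)
    K = (K + K.T) / 2.0
    if spec.family == "rbf":
        np.fill_diagonal(K, 1.0)
    return K


def center_gram(K, spec: KernelSpec | None = None, *, tol: float = 1e-8) -> CenteredGram:
    """Apply the four-term double-centering formula to a kernel matrix."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    asym = np.abs(K - K.T).max()
    if asym > tol:
        raise ValueError(f"K is asymmetric beyond tolerance ({asym:.2e} > {tol:.2e})")
    row_means = K.mean(axis=1)
    grand = float(row_means.mean())
    omega = K - row_means[:, None] - row_means[None, :] + grand
    omega = (omega + omega.T) / 2.0
    return CenteredGram(omega_c=omega, source_spec=spec, row_means=row_means, grand_mean=grand)


def cross_centered_kernel(
    model_X,
    test_X,
    spec: KernelSpec,
    *,
    train_gram: CenteredGram | None = None,
) -> np.ndarray:
    """Centered kernel values between test points and the training set.

    Entry (t, i) = K(x*_t, x_i) - mean_r K(x*_t, x_r) - mean_r K(x_i, x_r)
    + grand mean of the training kernel matrix, i.e. the inner product of
    the *training-mean-centered* feature maps of x*_t and x_i. With
    ``test_X is model_X`` this reproduces Omega_c.

    ``train_gram`` (a previous :func:`center_gram` result) skips recomputing
    the training centering statistics.
    """
    model_X = np.atleast_2d(np.asarray(model_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    if model_X.shape[1] != test_X.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {model_X.shape[1]} vs {test_X.shape[1]}"
        )
    if train_gram is None:
        train_gram = center_gram(gram_matrix(model_X, spec), spec)
    K_cross = _pairwise(test_X, model_X, spec)
    test_means = K_cross.mean(axis=1)
    return (
        K_cross
        - test_means[:, None]
        - train_gram.row_means[None, :]
        + train_gram.grand_mean
    )
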