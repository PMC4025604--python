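"""Kernel PCA via the centered-Gram eigenproblem, in the LS-SVM formulation.

Maximizing the variance of projections v'(phi(x_k) - mu_phi) subject to a
ridge penalty on v yields, after eliminating the primal variables, the dual
eigenproblem

    Omega_c alpha = lambda alpha,

where Omega_c is the double-centered kernel matrix and lambda = 1/gamma.
Each eigenvector alpha^(n) defines a score function

    z_n(x) = sum_i alpha_i^(n) K_c(x_i, x)

with K_c the training-centered kernel, so training scores are exactly
lambda_n alpha^(n). Linear PCA is the linear-kernel special case: the
eigenvalues of the centered linear Gram equal the squared singular values of
the column-centered data matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionDataset
from .kernels import CenteredGram, KernelSpec, center_gram, cross_centered_kernel, gram_matrix

__all__ = ["KPCAModel", "ScoreMatrix", "fit_kpca", "score", "fit_linear_pca"]

_EIGENVALUE_FLOOR = 1e-12


@dataclass
class KPCAModel:
    """Fitted eigendecomposition of the centered Gram matrix.

    alphas : (N, k) dual coefficients, unit-norm columns (one per retained
        component), sign-fixed so each column's largest-magnitude entry is
        positive.
    eigenvalues : (k,) nonincreasing, variance units.
    centering : training kernel row means / grand mean, required to score
        out-of-sample points with the same centered feature map.
    """

    spec: KernelSpec
    train_X: np.ndarray
    alphas: np.ndarray
    eigenvalues: np.ndarray
    k: int
    centering: CenteredGram

    def to_json(self) -> str:
        payload = {
            "spec": {
                "family": self.spec.family,
                "h": self.spec.h,
                "degree": self.spec.degree,
                "offset": self.spec.offset,
            },
            "train_X": self.train_X.tolist(),
            "alphas": self.alphas.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "k": self.k,
            "row_means": self.centering.row_means.tolist(),
            "grand_mean": self.centering.grand_mean,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "KPCAModel":
        p = json.loads(text)
        spec = KernelSpec(**p["spec"])
        centering = CenteredGram(
            omega_c=np.empty((0, 0)),
            source_spec=spec,
            row_means=np.asarray(p["row_means"], dtype=float),
            grand_mean=float(p["grand_mean"]),
        )
        return cls(
            spec=spec,
            train_X=np.asarray(p["train_X"], dtype=float),
            alphas=np.asarray(p["alphas"], dtype=float),
            eigenvalues=np.asarray(p["eigenvalues"], dtype=float),
            k=int(p["k"]),
            centering=centering,
        )


@dataclass
class ScoreMatrix:
    """Projections of M points onto the retained kernel principal components."""

    scores: np.ndarray
    component_ids: np.ndarray


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, ExpressionDataset):
        return data.X
    return np.atleast_2d(np.asarray(data, dtype=float))


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (determinism)."""
    idx = np.abs(vectors).argmax(axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def eigendecompose_centered(omega_c: np.ndarray, k: int):
    """Top-k eigenpairs of a centered Gram matrix, descending, sign-fixed."""
    eigvals, eigvecs = np.linalg.eigh(omega_c)
    order = np.argsort(eigvals)[::-1][:k]
    lam = eigvals[order]
    alphas = _fix_signs(eigvecs[:, order])
    return lam, alphas


def fit_kpca(
    data,
    spec: KernelSpec,
    k: int,
    *,
    precomputed_gram: np.ndarray | None = None,
) -> KPCAModel:
    """Fit kernel PCA: top-k eigenpairs of the centered Gram matrix.

    ``k`` must be at most N-1 (the centered Gram has rank <= N-1).
    Deterministic: eigenvector signs follow the largest-entry-positive
    convention. Components with eigenvalue below 1e-12 are kept with a
    warning (they carry essentially no variance).
    """
    X = _as_matrix(data)
    n = X.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= N-1 = {n - 1}, got {k}")
    K = gram_matrix(X, spec) if precomputed_gram is None else precomputed_gram
    centered = center_gram(K, spec)
    lam, alphas = eigendecompose_centered(centered.omega_c, k)
    if (lam < _EIGENVALUE_FLOOR).any():
        warnings.warn(
            "retained component(s) with eigenvalue below 1e-12; they carry "
            "negligible variance",
            stacklevel=2,
        )
    return KPCAModel(
        spec=spec,
        train_X=X,
        alphas=alphas,
        eigenvalues=lam,
        k=k,
        centering=centered,
    )


def score(model: KPCAModel, points, *, centered: bool = True) -> ScoreMatrix:
    """Score variables z_n(x) of ``points`` on the retained components.

    With ``centered=True`` (default) the training-centered kernel is used,
    consistent with the dual problem on Omega_c; for training points column
    n then equals lambda_n alpha^(n). ``centered=False`` evaluates the raw
    kernel expansion sum_i alpha_i^(n) K(x_i, x) instead.
    """
    P = _as_matrix(points)
    if P.shape[1] != model.train_X.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: model has {model.train_X.shape[1]}, "
            f"points have {P.shape[1]}"
        )
    if centered:
        Kc = cross_centered_kernel(
            model.train_X, P, model.spec, train_gram=model.centering
        )
    else:
        from .kernels import _pairwise

        Kc = _pairwise(P, model.train_X, model.spec)
    return ScoreMatrix(
        scores=Kc @ model.alphas,
        component_ids=np.arange(1, model.k + 1),
    )


def fit_linear_pca(data, k: int) -> KPCAModel:
    """Linear PCA through the same centered-Gram pipeline (linear kernel)."""
    return fit_kpca(data, KernelSpec("linear"), k)
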