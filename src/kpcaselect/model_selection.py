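"""Leave-one-out selection of the RBF bandwidth and component count for KPCA.

The criterion treats kernel PCA like a density estimator whose smoothing
parameter can be chosen by cross-validation: for each held-out sample j, the
model is refit on the remaining N-1 samples and the n-th score function
z_n^(-j)(.) is evaluated at all N samples (the held-out one scored
out-of-sample). The size of that score profile, measured by a trapezoidal
integral of its absolute values, rewards bandwidths whose components spread
the data. Summing over components and held-out samples gives

    J(h, k) = (1/N) sum_{n<=k} sum_{j<=N} integral |z_n^(-j)|,

maximized over a bandwidth grid; the component count is then picked where
the marginal gain of adding a component collapses (elbow rule), since each
added component contributes a nonnegative term. The linear-kernel
specialization J(k) selects the number of ordinary principal components with
the same machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy.spatial.distance import pdist, squareform

from .data_io import ExpressionDataset
from .kernels import KernelSpec, center_gram, gram_matrix
from .kpca import eigendecompose_centered

__all__ = [
    "SelectionSurface",
    "loo_score_integral",
    "criterion_J",
    "select_bandwidth_and_k",
    "select_pca_components",
    "default_bandwidth_grid",
    "elbow_components",
]


@dataclass
class SelectionSurface:
    """The criterion J evaluated on a (bandwidth x components) grid.

    J[i, j] is the criterion at ``h_grid[i]``, ``k_grid[j]`` (for the
    PCA variant the h axis has a single placeholder row). ``rescaled``
    records whether J was divided by its maximum (the argmax is invariant).
    """

    h_grid: np.ndarray
    k_grid: np.ndarray
    J: np.ndarray
    h_hat: float | None
    k_hat: int
    cv_mode: str
    rescaled: bool = False

    def to_long_frame(self):
        """(h, k, J) long-format table for export."""
        import pandas as pd

        h = np.repeat(self.h_grid if self.h_grid.size else [np.nan], len(self.k_grid))
        k = np.tile(self.k_grid, max(len(self.h_grid), 1))
        return pd.DataFrame({"h": h, "k": k, "J": self.J.ravel()})

    def summary(self) -> dict:
        return {
            "h_hat": self.h_hat,
            "k_hat": int(self.k_hat),
            "cv_mode": self.cv_mode,
            "h_grid": self.h_grid.tolist(),
            "k_grid": self.k_grid.tolist(),
        }


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, ExpressionDataset):
        return data.X
    return np.atleast_2d(np.asarray(data, dtype=float))


def _trapezoid_abs(scores: np.ndarray, sort_abscissae: bool = False) -> np.ndarray:
    """Unit-spaced trapezoidal integral of |scores| per column.

    Default: samples in canonical dataset order on a unit-spaced axis.
    ``sort_abscissae`` instead sorts each profile by the component-1 score
    (alternative integration reading; changes values, rarely the argmax).
    """
    a = np.abs(scores)
    if sort_abscissae and scores.shape[1] >= 1:
        order = np.argsort(scores[:, 0])
        a = a[order]
    return np.trapezoid(a, axis=0)


def _holdout_integrals(
    K: np.ndarray,
    holdout: np.ndarray,
    k_max: int,
    sort_abscissae: bool = False,
) -> np.ndarray:
    """Per-component integrals of |z_n^(-holdout)| over all N samples.

    ``K`` is the full uncentered N x N kernel matrix; the model is fit on
    the complement of ``holdout`` and its score functions evaluated at every
    sample via the training-centered cross kernel. Components beyond the
    rank of the reduced problem contribute 0.
    """
    n = K.shape[0]
    keep = np.setdiff1d(np.arange(n), holdout)
    m = keep.size
    k_eff = min(k_max, m - 1)
    Kt = K[np.ix_(keep, keep)]
    centered = center_gram(Kt)
    lam, alphas = eigendecompose_centered(centered.omega_c, k_eff)

    K_cross = K[:, keep]
    cross_means = K_cross.mean(axis=1)
    Kc = K_cross - cross_means[:, None] - centered.row_means[None, :] + centered.grand_mean
    scores = Kc @ alphas  # (n, k_eff)

    out = np.zeros(k_max)
    out[:k_eff] = _trapezoid_abs(scores, sort_abscissae)
    if k_eff < k_max:
        warnings.warn(
            f"components beyond rank {k_eff} of the reduced problem contribute 0",
            stacklevel=2,
        )
    return out


def loo_score_integral(data, spec: KernelSpec, n: int, j: int) -> float:
    """Integral of |z_n^(-j)| over all samples (component n, sample j out)."""
    X = _as_matrix(data)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for leave-one-out scoring")
    if not 1 <= n <= X.shape[0] - 2:
        raise ValueError(f"component index n={n} out of range")
    K = gram_matrix(X, spec)
    return float(_holdout_integrals(K, np.array([j]), n)[n - 1])


def _fold_assignment(n: int, v: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, v)]


def _criterion_profile(
    K: np.ndarray,
    k_max: int,
    folds: list[np.ndarray],
    sort_abscissae: bool = False,
) -> np.ndarray:
    """Cumulative criterion J(., k) for k = 1..k_max at one bandwidth.

    For a fold of size g, its fitted model is shared by all g held-out
    members, so the fold contributes g times its per-component integrals.
    """
    n = K.shape[0]
    totals = np.zeros(k_max)
    for fold in folds:
        totals += fold.size * _holdout_integrals(K, fold, k_max, sort_abscissae)
    profile = np.cumsum(totals) / n
    bad = ~np.isfinite(profile)
    if bad.any():
        warnings.warn("non-finite criterion values set to 0", stacklevel=2)
        profile[bad] = 0.0
    return profile


def _resolve_cv(cv, n: int, seed: int) -> tuple[list[np.ndarray], str]:
    if cv == "loo":
        return [np.array([j]) for j in range(n)], "loo"
    if isinstance(cv, tuple) and len(cv) == 2 and cv[0] == "vfold":
        v = int(cv[1])
    elif isinstance(cv, int):
        v = cv
    else:
        raise ValueError(f"cv must be 'loo', ('vfold', v) or an int, got {cv!r}")
    if not 2 <= v <= n:
        raise ValueError(f"v must be in [2, N], got {v}")
    return _fold_assignment(n, v, seed), f"vfold({v})"


def criterion_J(
    data,
    spec: KernelSpec,
    k: int,
    cv="loo",
    seed: int = 0,
    *,
    sort_abscissae: bool = False,
) -> float:
    """The selection criterion J(h, k) for a single kernel spec and k.

    ``cv`` is ``"loo"`` or ``("vfold", v)``; the seed only randomizes fold
    assignment (leave-one-out is seed-free). ``k = 0`` returns 0.
    """
    X = _as_matrix(data)
    n = X.shape[0]
    if k == 0:
        return 0.0
    if not 1 <= k <= n - 2:
        raise ValueError(f"k must satisfy 0 <= k <= N-2 = {n - 2}, got {k}")
    folds, _ = _resolve_cv(cv, n, seed)
    K = gram_matrix(X, spec)
    return float(_criterion_profile(K, k, folds, sort_abscissae)[k - 1])


def default_bandwidth_grid(X, num: int = 30) -> np.ndarray:
    """Log-spaced bandwidths from 0.1x to 10x the median pairwise distance."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    med = float(np.median(pdist(X)))
    if med <= 0:
        raise ValueError("median pairwise distance is 0 (all samples identical)")
    return np.geomspace(0.1 * med, 10.0 * med, num)


def elbow_components(profile: np.ndarray, eps: float = 0.01) -> int:
    """Smallest k whose next marginal gain drops below eps x max gain.

    ``profile`` holds J(k) for k = 1..k_max; gains are J(k) - J(k-1) with
    J(0) = 0. Returns k_max when no gain ever collapses.
    """
    gains = np.diff(profile, prepend=0.0)
    threshold = eps * gains.max()
    for k in range(1, len(profile)):
        if gains[k] < threshold:
            return k
    return len(profile)


def select_bandwidth_and_k(
    data,
    h_grid=None,
    k_max: int | None = None,
    cv="loo",
    seed: int = 0,
    *,
    eps: float = 0.01,
    rescale: bool = True,
    sort_abscissae: bool = False,
    n_jobs: int = 1,
) -> SelectionSurface:
    """Grid-search the criterion surface J(h, k) for RBF kernel PCA.

    The bandwidth maximizing J at the full component budget k_max is
    selected; the component count is then the elbow of the J(h_hat, .)
    profile. The returned surface is rescaled to maximum 1 by default
    (argmax-invariant); pass ``rescale=False`` for raw values.

    Leave-one-out is the default; ``cv=("vfold", v)`` shares each fold's
    model across its members (v = 10 is a sensible fallback for N > 150).
    ``n_jobs`` parallelizes over the bandwidth grid; results are collected
    in grid order so the surface is identical for any worker count.
    """
    X = _as_matrix(data)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if h_grid is None:
        h_grid = default_bandwidth_grid(X)
    h_grid = np.asarray(h_grid, dtype=float)
    if h_grid.size == 0 or (h_grid <= 0).any():
        raise ValueError("h_grid must be nonempty and strictly positive")
    if k_max is None:
        k_max = n - 2
    if not 1 <= k_max <= n - 2:
        raise ValueError(f"k_max must satisfy 1 <= k_max <= N-2 = {n - 2}")

    folds, cv_mode = _resolve_cv(cv, n, seed)
    d2 = squareform(pdist(X, "sqeuclidean"))

    def one_bandwidth(h: float) -> np.ndarray:
        K = np.exp(-d2 / (2.0 * h * h))
        return _criterion_profile(K, k_max, folds, sort_abscissae)

    if n_jobs == 1:
        rows = [one_bandwidth(h) for h in h_grid]
    else:
        rows = Parallel(n_jobs=n_jobs)(delayed(one_bandwidth)(h) for h in h_grid)
    J = np.vstack(rows)

    i_hat = int(np.argmax(J[:, -1]))
    h_hat = float(h_grid[i_hat])
    k_hat = elbow_components(J[i_hat], eps)
    if rescale and J.max() > 0:
        J = J / J.max()
    return SelectionSurface(
        h_grid=h_grid,
        k_grid=np.arange(1, k_max + 1),
        J=J,
        h_hat=h_hat,
        k_hat=k_hat,
        cv_mode=cv_mode,
        rescaled=rescale,
    )


def select_pca_components(
    data,
    k_max: int | None = None,
    cv="loo",
    seed: int = 0,
    *,
    eps: float = 0.01,
    rescale: bool = True,
    sort_abscissae: bool = False,
) -> SelectionSurface:
    """Component-count selection for linear PCA: the criterion J(k).

    Same leave-one-out machinery with the linear kernel; the surface has a
    single row over k and no bandwidth.
    """
    X = _as_matrix(data)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if k_max is None:
        k_max = n - 2
    if not 1 <= k_max <= n - 2:
        raise ValueError(f"k_max must satisfy 1 <= k_max <= N-2 = {n - 2}")
    folds, cv_mode = _resolve_cv(cv, n, seed)
    K = gram_matrix(X, KernelSpec("linear"))
    profile = _criterion_profile(K, k_max, folds, sort_abscissae)
    k_hat = elbow_components(profile, eps)
    J = profile[None, :]
    if rescale and J.max() > 0:
        J = J / J.max()
    return SelectionSurface(
        h_grid=np.array([]),
        k_grid=np.arange(1, k_max + 1),
        J=J,
        h_hat=None,
        k_hat=k_hat,
        cv_mode=cv_mode,
        rescaled=rescale,
    )


def plot_surface(surface: SelectionSurface, ax=None):
    """Heat map of the J(h, k) surface (or a line for the PCA variant)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if surface.h_grid.size == 0:
        ax.plot(surface.k_grid, surface.J.ravel(), marker="o")
        ax.set_xlabel("components k")
        ax.set_ylabel("J(k)")
        return ax
    mesh = ax.pcolormesh(
        surface.k_grid, surface.h_grid, surface.J, shading="nearest"
    )
    ax.set_yscale("log")
    ax.set_xlabel("components k")
    ax.set_ylabel("bandwidth h")
    ax.plot([surface.k_hat], [surface.h_hat], "r*", markersize=12)
    plt.colorbar(mesh, ax=ax, label="J(h, k)")
    return ax
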