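import numpy as np
import pytest

from kpcaselect import (
    KernelSpec,
    SyntheticSpec,
    criterion_J,
    default_bandwidth_grid,
    elbow_components,
    generate,
    loo_score_integral,
    select_bandwidth_and_k,
    select_pca_components,
)
from kpcaselect.kpca import fit_kpca, score


def naive_loo_integral(X, spec, n, j):
    """Longhand reimplementation with explicit loops (no shared code paths)."""
    N = X.shape[0]
    keep = [i for i in range(N) if i != j]
    m = len(keep)

    def kern(a, b):
        if spec.family == "linear":
            return float(np.dot(a, b))
        return float(np.exp(-np.sum((a - b) ** 2) / (2 * spec.h**2)))

    Kt = np.array([[kern(X[a], X[b]) for b in keep] for a in keep])
    grand = Kt.mean()
    rowm = Kt.mean(axis=1)
    Oc = np.array(
        [[Kt[a, b] - rowm[a] - rowm[b] + grand for b in range(m)] for a in range(m)]
    )
    w, V = np.linalg.eigh(Oc)
    alpha = V[:, np.argsort(w)[::-1][n - 1]]
    absscores = []
    for t in range(N):
        kt = np.array([kern(X[t], X[i]) for i in keep])
        val = float(np.sum(alpha * (kt - kt.mean() - rowm + grand)))
        absscores.append(abs(val))
    return sum(absscores) - 0.5 * (absscores[0] + absscores[-1])


class TestLooScoreIntegral:
    def test_identical_samples_give_zero(self):
        X = np.ones((5, 3))
        assert loo_score_integral(X, KernelSpec("rbf", h=1.0), 1, 0) == pytest.approx(0.0, abs=1e-10)

    def test_matches_longhand_linear(self, rng):
        X = rng.normal(size=(5, 3))
        spec = KernelSpec("linear")
        for j in range(5):
            for n in (1, 2, 3):
                got = loo_score_integral(X, spec, n, j)
                ref = naive_loo_integral(X, spec, n, j)
                assert got == pytest.approx(ref, abs=1e-10)

    def test_linear_kernel_homogeneity(self, rng):
        """Scaling X by c scales the linear-kernel integral by c^2.

        Scores are quadratic in the data under the linear kernel (Gram
        entries scale by c^2, unit-norm eigenvectors unchanged), so the
        criterion's argmax over scale-free linear problems is stable.
        """
        X = rng.normal(size=(6, 3))
        spec = KernelSpec("linear")
        base = loo_score_integral(X, spec, 1, 2)
        for c in (0.5, 2.0, 7.0):
            scaled = loo_score_integral(c * X, spec, 1, 2)
            assert scaled == pytest.approx(c**2 * base, rel=1e-8)


class TestCriterionJ:
    def test_zero_components(self, rng):
        X = rng.normal(size=(6, 3))
        assert criterion_J(X, KernelSpec("rbf", h=1.0), 0) == 0.0

    def test_monotone_in_k(self, rng):
        X = rng.normal(size=(7, 4))
        spec = KernelSpec("rbf", h=1.5)
        values = [criterion_J(X, spec, k) for k in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_loo_equals_n_fold(self, rng):
        X = rng.normal(size=(6, 3))
        spec = KernelSpec("rbf", h=1.2)
        loo = criterion_J(X, spec, 2, cv="loo")
        vfold = criterion_J(X, spec, 2, cv=("vfold", 6), seed=3)
        assert loo == pytest.approx(vfold, rel=1e-12)

    def test_k_out_of_range(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            criterion_J(X, KernelSpec("rbf", h=1.0), 4)


class TestSelectBandwidthAndK:
    def test_rescaled_surface_max_one(self, rng):
        X = rng.normal(size=(8, 4))
        surf = select_bandwidth_and_k(X, h_grid=np.geomspace(0.5, 5, 5), k_max=4)
        assert surf.J.max() == pytest.approx(1.0)
        assert surf.J.min() >= 0.0

    def test_rescaling_preserves_argmax(self, rng):
        X = rng.normal(size=(8, 4))
        grid = np.geomspace(0.5, 5, 5)
        raw = select_bandwidth_and_k(X, h_grid=grid, k_max=4, rescale=False)
        scaled = select_bandwidth_and_k(X, h_grid=grid, k_max=4, rescale=True)
        assert raw.h_hat == scaled.h_hat
        assert raw.k_hat == scaled.k_hat
        np.testing.assert_allclose(raw.J / raw.J.max(), scaled.J, atol=1e-12)

    def test_selection_attains_grid_optimum(self, rng):
        X = rng.normal(size=(8, 4))
        surf = select_bandwidth_and_k(X, h_grid=np.geomspace(0.3, 8, 6), k_max=4, rescale=False)
        i = np.where(surf.h_grid == surf.h_hat)[0][0]
        assert surf.J[i, -1] == surf.J[:, -1].max()

    def test_bandwidth_tracks_data_scale(self):
        """On shell data the selected bandwidth follows the latent scale s
        (within the decade centered on s) across seeds and scales."""
        hits = 0
        for i, s in enumerate([0.5, 2.0, 20.0] * 3):
            data = generate(
                SyntheticSpec(
                    structure="radial", effect=1.0, scale=s, noise_sd=0.05 * s, seed=500 + i
                )
            )
            surf = select_bandwidth_and_k(data, k_max=6)
            if abs(np.log10(surf.h_hat / s)) <= 0.5:
                hits += 1
        assert hits >= 8

    def test_invalid_grids(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError):
            select_bandwidth_and_k(X, h_grid=np.array([]))
        with pytest.raises(ValueError):
            select_bandwidth_and_k(X, h_grid=np.array([-1.0]))
        with pytest.raises(ValueError):
            select_bandwidth_and_k(X, k_max=10)

    def test_worker_count_does_not_change_surface(self, rng):
        X = rng.normal(size=(7, 3))
        grid = np.geomspace(0.5, 4, 4)
        a = select_bandwidth_and_k(X, h_grid=grid, k_max=3, n_jobs=1)
        b = select_bandwidth_and_k(X, h_grid=grid, k_max=3, n_jobs=2)
        np.testing.assert_array_equal(a.J, b.J)

    def test_sign_flip_invariance(self, rng):
        """J depends on |scores| only, so the eigensolver's sign freedom is
        immaterial: reflecting the data (which flips score signs under the
        linear kernel) leaves the linear criterion unchanged."""
        X = rng.normal(size=(7, 3))
        a = select_pca_components(X, k_max=4, rescale=False)
        b = select_pca_components(-X, k_max=4, rescale=False)
        np.testing.assert_allclose(a.J, b.J, atol=1e-9)


class TestSelectPCAComponents:
    def test_rank_one_data_selects_one_component(self):
        data = generate(
            SyntheticSpec(
                structure="linear-shift",
                informative_dim=1,
                effect=0.0,
                scale=1.0,
                noise_sd=0.01,
                seed=5,
            )
        )
        surf = select_pca_components(data, k_max=8)
        assert surf.k_hat == 1

    def test_profile_monotone(self, rng):
        X = rng.normal(size=(8, 5))
        surf = select_pca_components(X, k_max=5, rescale=False)
        assert (np.diff(surf.J.ravel()) >= -1e-12).all()

    def test_surface_export(self, rng, tmp_path):
        X = rng.normal(size=(7, 3))
        surf = select_bandwidth_and_k(X, h_grid=np.geomspace(0.5, 4, 3), k_max=3)
        frame = surf.to_long_frame()
        assert list(frame.columns) == ["h", "k", "J"]
        assert len(frame) == 9
        summary = surf.summary()
        assert summary["k_hat"] == surf.k_hat


class TestElbowRule:
    def test_flat_tail_cut(self):
        profile = np.array([1.0, 1.9, 2.0, 2.001, 2.002])
        assert elbow_components(profile, eps=0.01) == 3

    def test_no_collapse_returns_k_max(self):
        profile = np.cumsum(np.ones(5))
        assert elbow_components(profile, eps=0.01) == 5


def test_default_bandwidth_grid_spans_two_decades(rng):
    X = rng.normal(size=(10, 4))
    grid = default_bandwidth_grid(X)
    assert len(grid) == 30
    assert grid[-1] / grid[0] == pytest.approx(100.0, rel=1e-9)


def test_duplicate_sample_near_idempotence(rng):
    """Appending an exact copy of a sample moves J only modestly (loose
    sanity check on leave-one-out stability)."""
    X = rng.normal(size=(7, 3))
    spec = KernelSpec("rbf", h=1.5)
    base = criterion_J(X, spec, 2)
    dup = criterion_J(np.vstack([X, X[0]]), spec, 2)
    assert abs(dup - base) / base < 0.5
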