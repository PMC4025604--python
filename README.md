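# kpcaselect

Kernel PCA with a data-driven bandwidth selection criterion, plus LS-SVM
classification, for high-dimensional two-class expression data (genes ≫
samples: microarray and similar assays).

## The problem

Kernel PCA with an RBF kernel, K(x, x′) = exp(−‖x − x′‖² / 2h²), is a
powerful nonlinear dimensionality-reduction step before classification, but
it has two free parameters — the bandwidth *h* and the number of retained
components *k* — and, being unsupervised, offers no obvious validation
signal for choosing them. This package implements a leave-one-out criterion
in the spirit of least-squares cross-validation for kernel density
estimation: refit KPCA with sample *j* held out, evaluate the held-out score
functions z_n^(−j)(·) at all samples, and measure their total absolute size
by trapezoidal integration,

    J(h, k) = (1/N) Σ_{n≤k} Σ_{j≤N} ∫ |z_n^(−j)(x)| dx .

Maximizing J over a bandwidth grid picks the *h* whose components spread the
data most under cross-validation; the component count is then chosen where
the marginal gain of one more component collapses (elbow rule). The same
machinery with a linear kernel, J(k), selects the number of ordinary
principal components.

The KPCA itself is formulated as a least-squares SVM problem whose dual is
the eigenproblem Ω_c α = λα on the double-centered kernel matrix Ω_c, and
classification uses the LS-SVM dual: one bordered linear system

    [ 0   yᵀ       ] [ b ]   [ 0 ]
    [ y   Ω + I/γ  ] [ β ] = [ 1 ] ,   Ω_ij = y_i y_j K(x_i, x_j),

with decision values y(x) = Σ_k β_k y_k K(x, x_k) + b.

## Worked example

Concentric-shell data (40 samples, 200 features, both class means at the
origin) is the regime that motivates kernel PCA: no linear projection
separates the classes, but the radius does.

```python
from kpcaselect import (
    SyntheticSpec, generate, standardize, select_bandwidth_and_k,
    PipelineSpec, run_protocol, signed_rank_test,
)

data = generate(SyntheticSpec(structure="radial", effect=1.0, seed=7))

surface = select_bandwidth_and_k(standardize(data), k_max=10)
print(f"selected bandwidth h = {surface.h_hat:.2f}, components k = {surface.k_hat}")

kpca = run_protocol(data, PipelineSpec("kpca", "lin", k_max=10), repeats=10, seed=11)
pca = run_protocol(data, PipelineSpec("pca", "lin", k_max=10), repeats=10, seed=11)
print(f"KPCA(rbf) + LS-SVM  mean test AUC = {kpca.mean_auc:.3f} ({kpca.std_auc:.3f})")
print(f"PCA      + LS-SVM  mean test AUC = {pca.mean_auc:.3f} ({pca.std_auc:.3f})")
print(f"two-sided signed-rank p = {signed_rank_test(kpca.aucs, pca.aucs):.4f}")
```

Output:

```
selected bandwidth h = 11.19, components k = 10
KPCA(rbf) + LS-SVM  mean test AUC = 0.974 (0.062)
PCA      + LS-SVM  mean test AUC = 0.521 (0.158)
two-sided signed-rank p = 0.0020
```

The selected bandwidth sits near the typical pairwise distance of the
standardized data (≈ 19 here), tuned KPCA + LS-SVM reaches mean test AUC
0.97 over ten stratified 2/3–1/3 splits, linear PCA + LS-SVM stays at
chance, and the paired signed-rank test confirms the difference. Each
repeat selects (h, k) on its training split only and tunes the classifier's
regularization γ by stratified cross-validated AUC.

A command-line interface mirrors the library (`kpcaselect select | project
| train | evaluate | compare`); run `kpcaselect --help`.

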