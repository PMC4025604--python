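# Methods

## Kernel PCA as a least-squares SVM problem

Given samples x_1, …, x_N ∈ R^d, kernel PCA seeks directions v in the
kernel-induced feature space maximizing the variance of the centered
projections e_k = vᵀ(φ(x_k) − μ̂_φ), traded off against ‖v‖² by a
regularization constant γ. Eliminating the primal variables yields the dual
eigenproblem

    Ω_c α = λ α,    λ = 1/γ,

on the double-centered kernel matrix

    Ω_c[i,j] = K(x_i, x_j) − (1/N) Σ_r K(x_i, x_r)
               − (1/N) Σ_r K(x_j, x_r) + (1/N²) Σ_{r,s} K(x_r, x_s).

Kernels: RBF K(x, x′) = exp(−‖x − x′‖²/(2h²)) (note the 2h² in the
denominator — a common source of factor-√2 drift between implementations),
linear xᵀx′, and polynomial (xᵀx′ + c)^p with defaults c = 1, p = 3.

Conventions (the dual scale is not fixed by the optimization problem):

* Eigenvectors α⁽ⁿ⁾ have unit Euclidean norm — the plain symmetric
  eigenproblem convention — so training scores equal λ_n α⁽ⁿ⁾. Any fixed
  monotone rescaling applied uniformly across bandwidths leaves the
  selection criterion's argmax unchanged, so this choice is immaterial for
  selection.
* Signs are fixed by making each column's largest-magnitude entry positive,
  removing eigensolver nondeterminism. Downstream quantities are
  sign-insensitive (the criterion uses |z|; classifiers are retuned).
* Out-of-sample scores use the *training-centered* kernel consistently:
  z_n(x) = Σ_i α_i⁽ⁿ⁾ K_c(x_i, x), where K_c subtracts the test point's mean
  kernel to the training set, the training row means, and adds the training
  grand mean. The uncentered expansion Σ_i α_i⁽ⁿ⁾ K(x_i, x) is available
  via `score(..., centered=False)`.
* Linear PCA runs through the identical centered-Gram code path; the
  eigenvalues then equal the squared singular values of the column-centered
  data matrix.
* Eigendecomposition is a dense symmetric solve (`numpy.linalg.eigh`);
  sample counts in scope are at most a few hundred, so iterative solvers
  would add nondeterminism for no benefit. Within a degenerate eigenvalue's
  eigenspace the returned basis is arbitrary; see Numerical notes.

## The selection criterion

The bandwidth criterion treats the score variables like the quantity whose
"size" least-squares cross-validation maximizes in kernel density
estimation. For each held-out sample j, KPCA is refit on the other N − 1
samples and the held-out score function is integrated in absolute value:

    J(h, k) = (1/N) Σ_{n=1..k} Σ_{j=1..N} ∫ |z_n^(−j)(x)| dx.

Two aspects of this integral are underdetermined for d-dimensional x, and
the package fixes them as follows:

* **Integration rule.** |z_n^(−j)| is evaluated at all N training samples in
  canonical dataset order and integrated by the unit-spaced trapezoidal
  rule over the sample index — the L1 norm of the score vector up to
  halving of the two endpoints. This compares like with like across
  bandwidths, which is all an argmax needs. An alternative mode
  (`sort_abscissae=True`) sorts each profile by its component-1 score
  before integrating.
* **Evaluation points.** All N samples are scored, the held-out one
  out-of-sample. Scoring only the held-out point would collapse the
  integral to a single value and cannot drive a trapezoidal rule; using the
  full empirical sample as the integration proxy keeps the criterion a
  functional of the whole score function.

Selection rules:

* **Bandwidth.** J(·, k) is computed on a grid — by default 30
  log-spaced points from 0.1× to 10× the median pairwise Euclidean
  distance of the (standardized) data — and h_hat maximizes J at the full
  component budget k_max. Grids for reproduction studies should include the
  candidate values of interest explicitly.
* **Components.** J is a sum of nonnegative per-component terms, hence
  non-decreasing in k; an interior optimum cannot come from the raw
  maximization. k_hat is therefore the elbow: the smallest k whose next
  marginal gain J(h_hat, k+1) − J(h_hat, k) falls below ε × (largest
  marginal gain), ε = 0.01. The full surface is always returned so other
  rules can be applied. This elbow is an interpretation imposed on a
  monotone criterion, and is flagged as such.
* **Rescaling.** The returned surface is divided by its maximum
  (argmax-invariant); `rescale=False` gives raw values.
* **Cross-validation.** Leave-one-out by default; `cv=("vfold", v)` shares
  each fold's refit across the fold's members (the fold contributes its
  size times its per-component integrals). v = 10 is a sensible fallback
  beyond N ≈ 150, where LOO's N refits per grid point dominate runtime.
  The seed only randomizes fold assignment; LOO is seed-free. The
  bandwidth loop parallelizes over the grid (`n_jobs`), with results
  collected in grid order so the surface is bitwise independent of worker
  count.

The PCA variant J(k) is the linear-kernel specialization over k alone, with
the same elbow rule.

## LS-SVM classification

The classifier solves min ½‖w‖² + (γ/2) Σ e_k² subject to
y_k (wᵀφ(x_k) + b) = 1 − e_k, whose dual is the single bordered linear
system shown in the README, solved by a symmetric indefinite factorization
of the full (N+1)×(N+1) matrix — no elimination shortcuts, for
transparency; a singular system falls back to least squares with a warning.
Regularization γ (and, for an RBF classifier kernel, its bandwidth) is
tuned by stratified v-fold cross-validation maximizing validation AUC
(matching AUC reporting; default grid 10⁻³…10³, 13 log-spaced points, 10
folds, ties broken toward stronger regularization). AUC itself is the
Mann–Whitney rank statistic with ties counting ½.

## Evaluation protocol

Per repeat (30 by default): stratified split assigning 2/3 of each class to
training (per-class floors, deficit resolved toward the larger class);
feature-wise z-scoring with mean and *population* SD computed on the
training partition only and applied to both partitions (whole-data
standardization available for strict reproduction attempts; the
population-SD convention makes training columns have variance exactly 1 and
is switchable via `ddof`); selection of (h, k) on the training partition
only; projection of both partitions; γ tuning on training scores; test AUC
of the latent decision values. All randomness derives from one master seed,
so pipelines evaluated with the same seed share their splits and their
paired per-repeat AUCs feed a two-sided Wilcoxon signed-rank test
(zero differences dropped; exact null by dynamic programming over rank sums
for up to 25 non-zero differences — midranks handled by doubling — and a
normal approximation with continuity and tie corrections beyond).

## Synthetic data

The generator emulates the *shape* of two-class expression studies — N of
tens to low hundreds, d in the hundreds to thousands, balanced classes —
with a latent structure embedded into d dimensions by a seeded orthonormal
map (QR of a Gaussian matrix) plus independent Gaussian feature noise:

* `linear-shift` — Gaussian clouds with latent mean separation `effect`
  (an exactly label-symmetric null at effect 0);
* `radial` — concentric shells, class +1 at (1 + effect)× the radius of
  class −1, 5% radial jitter: identical class means, so linear methods are
  blind while a radius-sensitive kernel separates;
* `two-moons-embedded` — interleaved half-circles in a latent plane.

Defaults (20 samples per class, d = 200, latent dimension 5, effect 1,
noise SD 0.05, scale 1) keep leave-one-out selection fast while preserving
the genes ≫ samples regime; evaluation runs here use 10 protocol repeats
and a 10-component budget at these sizes, and a study at realistic scale
would raise N to ~100, d to ~10⁴ and repeats to 30. The generator does
*not* model batch effects, intensity-dependent variance, missing values, or
correlated noise, so passing tests demonstrate the machinery and the
criterion's scale-tracking behavior, not performance on real arrays.

On this radial design the selected bandwidth tracks the latent scale s
(empirically h_hat ≈ 1.3 s across seeds and two decades of s), which is the
parameter-recovery property the tests assert.

## Numerical notes

* Centered-Gram invariants: row sums 0 (tol 1e−8), symmetry 1e−10, smallest
  eigenvalue ≥ −1e−8 × largest. Asymmetry beyond 1e−8 is an error.
* When the RBF bandwidth is far below the data scale the Gram matrix
  approaches the identity and the centered spectrum degenerates; the
  per-component basis is then ill-conditioned and criterion values at such
  bandwidths should not be compared across implementations at tight
  tolerance (the criterion remains well-defined as a sum over the retained
  subspace).
* Components beyond the rank of a reduced (leave-one-out) problem
  contribute 0 with a warning; non-finite criterion entries are set to 0
  with a warning.
* Eigenvalue ties are ordered by the sign-fixed first differing
  coefficient — arbitrary within the eigenspace, documented as such.
* Constant features on the standardization reference are centered, not
  scaled (warning); loaders reject missing values outright — imputation is
  out of scope.

## Known limitations

* The criterion's integration measure is a modeling choice (see above), not
  a mathematically canonical object; conclusions about *absolute* J values
  across datasets are meaningless — only within-grid comparisons matter.
* The elbow rule's ε = 0.01 is a convention; profiles with slowly decaying
  gains select k_max.
* Grid-only bandwidth search; no continuous optimization over h, and the
  criterion is applied to the RBF family only.
* Binary classification only; no probabilistic outputs, no multiclass
  coding, no sparse approximations of the Gram matrix.
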