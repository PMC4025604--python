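"""Seeded generator of microarray-like two-class datasets.

Emulates the shape of public expression benchmarks — tens to hundreds of
samples, thousands of features, two classes — with a controllable latent
class structure:

* ``linear-shift``: classes are Gaussian clouds whose latent means differ by
  the effect size along one axis (linearly separable when the effect is
  large; an exact label-symmetric null when it is 0).
* ``radial``: both classes live on concentric shells in the latent space,
  class +1 at radius (1 + effect) times class -1's; the class means
  coincide, so no linear projection separates them while a radius-sensitive
  (RBF) kernel does.
* ``two-moons-embedded``: the classic interleaved half-circles in a latent
  plane.

The latent points are embedded into d ambient dimensions through a seeded
orthonormal map (QR factorization of a Gaussian matrix), and independent
Gaussian noise of a chosen SD is added to every ambient feature; the
remaining directions therefore carry pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionDataset

__all__ = ["SyntheticSpec", "generate"]

_STRUCTURES = ("linear-shift", "radial", "two-moons-embedded")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-class expression-like dataset.

    n_per_class : samples per class (default 20, i.e. N = 40 — small enough
        for fast leave-one-out, shaped like the low end of real studies; a
        "paper-scale" run would use ~100 samples and ~10,000 features).
    d : ambient feature count (default 200).
    informative_dim : latent dimension carrying the class structure.
    structure : one of "linear-shift", "radial", "two-moons-embedded".
    effect : class separation in latent units (shift distance, relative
        radius gap, or moon offset).
    noise_sd : SD of the ambient Gaussian noise on every feature.
    scale : overall latent scale s; distances in the informative subspace
        are proportional to it.
    """

    n_per_class: int = 20
    d: int = 200
    informative_dim: int = 5
    structure: str = "radial"
    effect: float = 1.0
    noise_sd: float = 0.05
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ValueError(f"structure must be one of {_STRUCTURES}")
        if not 1 <= self.informative_dim <= self.d:
            raise ValueError("need d >= informative_dim >= 1")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise sd must be positive")
        if self.structure == "two-moons-embedded" and self.informative_dim < 2:
            raise ValueError("two-moons needs informative_dim >= 2")


def _latent_points(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n, q, s = spec.n_per_class, spec.informative_dim, spec.scale
    if spec.structure == "linear-shift":
        Z = rng.normal(0.0, s, size=(2 * n, q))
        Z[:n, 0] -= 0.5 * spec.effect * s
        Z[n:, 0] += 0.5 * spec.effect * s
        return Z
    if spec.structure == "radial":
        u = rng.normal(size=(2 * n, q))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = np.concatenate(
            [np.full(n, s), np.full(n, s * (1.0 + spec.effect))]
        )
        radii = radii * (1.0 + 0.05 * rng.normal(size=2 * n))  # thin shells
        return u * radii[:, None]
    # two moons in the first two latent coordinates
    t = rng.uniform(0.0, np.pi, size=(2 * n,))
    Z = np.zeros((2 * n, q))
    Z[:n, 0] = s * np.cos(t[:n])
    Z[:n, 1] = s * np.sin(t[:n])
    Z[n:, 0] = s * (1.0 - np.cos(t[n:]))
    Z[n:, 1] = s * (0.5 * spec.effect - np.sin(t[n:]))
    return Z


def generate(spec: SyntheticSpec) -> ExpressionDataset:
    """Draw a dataset: latent structure, orthonormal embedding, ambient noise.

    Deterministic given ``spec.seed``; class labels are balanced with class
    -1 first (the generator's canonical order — shuffling is the splitter's
    job).
    """
    rng = np.random.default_rng(spec.seed)
    Z = _latent_points(spec, rng)
    basis, _ = np.linalg.qr(rng.normal(size=(spec.d, spec.informative_dim)))
    X = Z @ basis.T
    X += rng.normal(0.0, spec.noise_sd, size=X.shape)
    n = spec.n_per_class
    y = np.concatenate([-np.ones(n, dtype=int), np.ones(n, dtype=int)])
    return ExpressionDataset(
        X=X,
        y=y,
        sample_ids=[f"s{i:04d}" for i in range(2 * n)],
        feature_ids=[f"g{j:05d}" for j in range(spec.d)],
        label_mapping={"classA": -1, "classB": 1},
    )
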