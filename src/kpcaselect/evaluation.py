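"""Experimental harness: repeated stratified splits, AUC, signed-rank tests.

The protocol mirrors the standard microarray benchmark design: per repeat,
2/3 of each class is drawn for training, features are standardized on the
training partition, the dimensionality-reduction parameters (bandwidth h and
component count k) are selected on the training data only, the classifier's
regularization is tuned by cross-validation, and the test AUC of the latent
decision values is recorded. Thirty repeats by default; methods run with the
same master seed share their splits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .data_io import ExpressionDataset, standardize, stratified_split
from .kernels import KernelSpec
from .kpca import fit_kpca, fit_linear_pca, score
from .lssvm import decision_values, fit_lssvm, tune_lssvm
from .model_selection import select_bandwidth_and_k, select_pca_components

__all__ = [
    "EvaluationReport",
    "PipelineSpec",
    "auc",
    "run_protocol",
    "signed_rank_test",
]

_KERNEL_ALIASES = {"lin": "linear", "linear": "linear", "rbf": "rbf", "poly": "polynomial", "polynomial": "polynomial"}


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney rank form; ties count 1/2.

    Equals the probability that a uniformly random positive sample receives
    a higher score than a uniformly random negative one.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos = labels == np.max(labels)
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0 or len(np.unique(labels)) != 2:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over the 2^n equiprobable sign assignments.

    Works on doubled ranks so midranks (ties) stay integral; the null
    distribution of 2*W+ is built by dynamic programming over the rank
    generating polynomial.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = (dist + shifted) / 2.0
    w2 = int(np.rint(2 * w_plus))
    p_low = dist[: w2 + 1].sum()
    p_high = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def signed_rank_test(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon's original treatment); ties in
    |difference| receive midranks. The null distribution is exact for up to
    25 non-zero differences and a normal approximation with continuity and
    tie correction beyond that. All-zero differences give p = 1 with a
    warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if d.size < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= 25:
        return _exact_signed_rank_p(ranks, w_plus)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    # continuity correction toward the mean
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


@dataclass(frozen=True)
class PipelineSpec:
    """A reduction + classification pipeline for :func:`run_protocol`.

    reduction : "whole" | "pca" | "kpca"
    classifier_kernel : "lin" | "rbf" | "poly" (the LS-SVM kernel)
    k_max : component budget for the selection criterion (None: N_train - 2,
        capped at 30 for tractability)
    cv : "loo" or ("vfold", v), forwarded to the selection criterion
    """

    reduction: str = "kpca"
    classifier_kernel: str = "lin"
    k_max: int | None = None
    cv: object = "loo"
    gamma_grid: tuple | None = None
    h_grid: tuple | None = None

    def label(self) -> str:
        return f"{self.reduction}+lssvm({self.classifier_kernel})"


@dataclass
class EvaluationReport:
    """Per-repeat test AUCs plus the selected hyperparameters."""

    method: str
    aucs: list[float]
    selected: list[dict]
    seeds: list[int]
    repeats: int
    failures: list[dict] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0

    @property
    def complete(self) -> bool:
        return len(self.aucs) == self.repeats

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "mean_auc": self.mean_auc,
                "std_auc": self.std_auc,
                "aucs": self.aucs,
                "selected": self.selected,
                "seeds": self.seeds,
                "repeats": self.repeats,
                "failures": self.failures,
                "complete": self.complete,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        p = json.loads(text)
        return cls(
            method=p["method"],
            aucs=p["aucs"],
            selected=p["selected"],
            seeds=p["seeds"],
            repeats=p["repeats"],
            failures=p.get("failures", []),
        )


def _run_one_repeat(
    data: ExpressionDataset, pipeline: PipelineSpec, repeat_seed: int, fraction: float
) -> tuple[float, dict]:
    plan = stratified_split(data, fraction, repeat_seed)
    std = standardize(data, plan.train_indices)
    train = std.subset(plan.train_indices)
    test = std.subset(plan.test_indices)
    chosen: dict = {}

    n_train = train.n_samples
    k_cap = pipeline.k_max if pipeline.k_max is not None else min(30, n_train - 2)
    k_cap = min(k_cap, n_train - 2)

    if pipeline.reduction == "whole":
        Ztr, Zte = train.X, test.X
    elif pipeline.reduction == "pca":
        surface = select_pca_components(train, k_max=k_cap, cv=pipeline.cv, seed=repeat_seed)
        model = fit_linear_pca(train, surface.k_hat)
        Ztr = score(model, train.X).scores
        Zte = score(model, test.X).scores
        chosen["k"] = int(surface.k_hat)
    elif pipeline.reduction == "kpca":
        h_grid = np.asarray(pipeline.h_grid) if pipeline.h_grid is not None else None
        surface = select_bandwidth_and_k(
            train, h_grid=h_grid, k_max=k_cap, cv=pipeline.cv, seed=repeat_seed
        )
        model = fit_kpca(train, KernelSpec("rbf", h=surface.h_hat), surface.k_hat)
        Ztr = score(model, train.X).scores
        Zte = score(model, test.X).scores
        chosen["h"] = float(surface.h_hat)
        chosen["k"] = int(surface.k_hat)
    else:
        raise ValueError(f"unknown reduction {pipeline.reduction!r}")

    clf_spec = KernelSpec(_KERNEL_ALIASES[pipeline.classifier_kernel])
    gamma_grid = np.asarray(pipeline.gamma_grid) if pipeline.gamma_grid is not None else None
    gamma, clf_spec = tune_lssvm(
        Ztr, train.y, clf_spec, gamma_grid=gamma_grid, seed=repeat_seed
    )
    chosen["gamma"] = float(gamma)
    if clf_spec.family == "rbf":
        chosen["classifier_h"] = float(clf_spec.h)
    model = fit_lssvm(Ztr, train.y, clf_spec, gamma)
    return auc(decision_values(model, Zte), test.y), chosen


def run_protocol(
    data: ExpressionDataset,
    method: PipelineSpec | str,
    repeats: int = 30,
    seed: int = 0,
    *,
    fraction: float = 2.0 / 3.0,
) -> EvaluationReport:
    """Repeated stratified-split evaluation of a pipeline on one dataset.

    Per repeat: split -> standardize on train -> select (h, k) on train
    only -> project -> tune gamma on train -> fit -> test AUC. All
    randomness derives from the master seed, so two methods evaluated with
    the same seed see identical splits. A repeat whose selection fails is
    recorded as missing and flagged in the report.
    """
    if isinstance(method, str):
        reduction, _, kern = method.partition("+lssvm")
        kern = kern.strip("()") or "lin"
        method = PipelineSpec(reduction=reduction, classifier_kernel=kern)
    rng = np.random.default_rng(seed)
    repeat_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=repeats)]
    aucs, selected, failures = [], [], []
    for r, rs in enumerate(repeat_seeds):
        try:
            value, chosen = _run_one_repeat(data, method, rs, fraction)
        except Exception as exc:  # selection/tuning failure: record, move on
            failures.append({"repeat": r, "reason": str(exc)})
            continue
        aucs.append(value)
        selected.append(chosen)
    return EvaluationReport(
        method=method.label(),
        aucs=aucs,
        selected=selected,
        seeds=repeat_seeds,
        repeats=repeats,
        failures=failures,
    )
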