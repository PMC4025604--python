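"""Loading, validation, standardization and splitting of expression datasets.

Datasets are sample-by-feature numeric matrices with a binary label per
sample, read from delimited text (samples in rows, header row of feature
identifiers, one label column). Labels are mapped to {-1, +1} with the
lexicographically smaller original label becoming -1; the mapping is kept on
the dataset so reports can show the original names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SplitPlan",
    "load_dataset",
    "standardize",
    "inverse_standardize",
    "stratified_split",
]


@dataclass
class ExpressionDataset:
    """Sample-by-feature expression matrix with binary labels.

    Attributes
    ----------
    X : (N, d) float array
        Expression values; z-score units once ``standardized`` is True.
    y : (N,) int array
        Class labels in {-1, +1}.
    sample_ids, feature_ids : lists of str
    standardized : bool
        True after :func:`standardize`; the reference-partition columns then
        have mean 0 and (population) variance 1.
    label_mapping : dict
        Original label value -> {-1, +1}.
    feature_means_, feature_sds_ : arrays or None
        Transform parameters retained for inverse-transforming.
    """

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    standardized: bool = False
    label_mapping: dict = field(default_factory=dict)
    feature_means_: np.ndarray | None = None
    feature_sds_: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D sample-by-feature matrix")
        n, d = self.X.shape
        if len(self.y) != n:
            raise ValueError(f"y has length {len(self.y)}, expected {n}")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal the number of samples")
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids length must equal the number of features")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        extra = set(np.unique(self.y)) - {-1, 1}
        if extra:
            raise ValueError(f"labels must be in {{-1, +1}}, found {sorted(extra)}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, indices) -> "ExpressionDataset":
        """Row subset preserving feature metadata and transform state."""
        indices = np.asarray(indices)
        return ExpressionDataset(
            X=self.X[indices],
            y=self.y[indices],
            sample_ids=[self.sample_ids[i] for i in indices],
            feature_ids=list(self.feature_ids),
            standardized=self.standardized,
            label_mapping=dict(self.label_mapping),
            feature_means_=self.feature_means_,
            feature_sds_=self.feature_sds_,
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        """Round-trippable DataFrame with original label names restored."""
        inverse = {v: k for k, v in self.label_mapping.items()}
        labels = [inverse.get(v, v) for v in self.y]
        df = pd.DataFrame(self.X, index=self.sample_ids, columns=self.feature_ids)
        df.insert(0, label_column, labels)
        return df


@dataclass(frozen=True)
class SplitPlan:
    """A stratified train/test partition of sample indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    fraction: float

    def __post_init__(self) -> None:
        train = set(self.train_indices.tolist())
        test = set(self.test_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    stem = str(path)
    if stem.endswith(".gz"):
        stem = stem[:-3]
    return "\t" if stem.endswith((".tsv", ".txt")) else ","


def load_dataset(
    path,
    label_column: str,
    *,
    delimiter: str | None = None,
    transpose: bool = False,
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path : str or path-like
        CSV/TSV file (optionally gzip-compressed), samples in rows, header
        row of feature identifiers, first column sample identifiers.
    label_column : str
        Column holding the two class labels.
    delimiter : str, optional
        Override the extension-based delimiter guess.
    transpose : bool
        Set for gene-by-sample files; the table is transposed before the
        label column is looked up.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    if transpose:
        df = df.T
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels_raw = df[label_column]
    features = df.drop(columns=[label_column])

    if features.isna().any().any() or labels_raw.isna().any():
        cells = [
            f"(row {df.index[i]!r}, column {df.columns[c]!r})"
            for i, c in zip(*np.where(df.isna().to_numpy()))
        ]
        raise ValueError("missing values at: " + ", ".join(cells[:20]))

    X = features.to_numpy(dtype=float)
    classes = sorted(labels_raw.unique(), key=str)
    if len(classes) != 2:
        raise ValueError(
            f"label column must have exactly two distinct values, found {classes}"
        )
    mapping = {classes[0]: -1, classes[1]: 1}
    y = labels_raw.map(mapping).to_numpy(dtype=int)
    return ExpressionDataset(
        X=X,
        y=y,
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in features.columns],
        label_mapping=mapping,
    )


def standardize(
    data: ExpressionDataset,
    reference_indices=None,
    *,
    ddof: int = 0,
) -> ExpressionDataset:
    """Z-score every feature using statistics from the reference partition.

    Means and standard deviations are computed on ``reference_indices`` only
    (the training partition in the evaluation protocol, preventing leakage;
    pass ``None`` for whole-data standardization) and applied to all samples.
    The population-SD convention (``ddof=0``) makes the reference columns
    have variance exactly 1; pass ``ddof=1`` for the sample-SD convention.

    Features constant on the reference set are centered and left unscaled,
    with a warning.
    """
    if reference_indices is None:
        reference_indices = np.arange(data.n_samples)
    reference_indices = np.asarray(reference_indices)
    if reference_indices.size == 0:
        raise ValueError("reference set must be nonempty")
    ref = data.X[reference_indices]
    means = ref.mean(axis=0)
    sds = ref.std(axis=0, ddof=ddof)
    zero = sds <= 0
    if zero.any():
        names = [data.feature_ids[i] for i in np.where(zero)[0][:10]]
        warnings.warn(
            f"{int(zero.sum())} feature(s) constant on the reference set "
            f"(e.g. {names}); centered but not scaled",
            stacklevel=2,
        )
        sds = np.where(zero, 1.0, sds)
    out = replace(
        data,
        X=(data.X - means) / sds,
        standardized=True,
        feature_means_=means,
        feature_sds_=sds,
    )
    return out


def inverse_standardize(data: ExpressionDataset) -> ExpressionDataset:
    """Undo :func:`standardize` using the stored means/SDs."""
    if data.feature_means_ is None or data.feature_sds_ is None:
        raise ValueError("dataset carries no standardization parameters")
    return replace(
        data,
        X=data.X * data.feature_sds_ + data.feature_means_,
        standardized=False,
        feature_means_=None,
        feature_sds_=None,
    )


def stratified_split(
    data: ExpressionDataset, fraction: float, seed: int
) -> SplitPlan:
    """Random stratified split: per class, ``fraction`` of samples train.

    Per-class training counts are floors of ``fraction * class_size``; any
    deficit relative to ``round(fraction * N)`` is resolved toward the larger
    class. Deterministic given ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(data.y, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples to split")

    floors = np.floor(fraction * counts).astype(int)
    deficit = int(round(fraction * data.n_samples)) - int(floors.sum())
    order = np.argsort(-counts)  # larger classes absorb the deficit first
    for idx in order:
        if deficit <= 0:
            break
        if floors[idx] < counts[idx] - 1:
            floors[idx] += 1
            deficit -= 1
    # every class keeps at least one training and one test sample
    floors = np.clip(floors, 1, counts - 1)

    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for cls, n_train in zip(classes, floors):
        members = np.where(data.y == cls)[0]
        perm = rng.permutation(members)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return SplitPlan(
        train_indices=np.sort(np.concatenate(train)),
        test_indices=np.sort(np.concatenate(test)),
        seed=seed,
        fraction=fraction,
    )
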