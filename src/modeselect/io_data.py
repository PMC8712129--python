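"""Data model for labeled expression matrices, file I/O, fold splitting, run config.

A :class:`Dataset` holds a samples x genes matrix of continuous expression
values with a binary class label per sample.  Matrix reads go through the
``matrix`` property, which counts accesses; the outer cross-validation
protocol uses the counter to prove that feature selection never touches
held-out rows.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Dataset",
    "FoldPlan",
    "RunConfig",
    "load_dataset",
    "write_dataset",
    "stratified_kfold",
    "default_filter_lambda",
]


@dataclass
class Dataset:
    """Expression matrix with binary labels.

    ``matrix`` is exposed through a counting property so that evaluation
    protocols can assert which splits were actually read.
    """

    _matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    n_reads: int = 0

    def __init__(self, matrix, labels, feature_names=None, sample_ids=None):
        matrix = np.asarray(matrix, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (samples x features)")
        n, m = matrix.shape
        if len(labels) != n:
            raise ValueError("labels length does not match number of samples")
        if feature_names is None:
            feature_names = [f"g{j}" for j in range(m)]
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(n)]
        if len(feature_names) != m:
            raise ValueError("feature_names length does not match number of features")
        if len(sample_ids) != n:
            raise ValueError("sample_ids length does not match number of samples")
        if np.isnan(matrix).any():
            raise ValueError("missing values in matrix are not supported")
        uniq = np.unique(labels)
        if len(uniq) != 2:
            raise ValueError("not a binary problem")
        if not np.array_equal(uniq, [0, 1]):
            raise ValueError("labels must be coded as {0,1}")
        self._matrix = matrix
        self.labels = labels
        self.feature_names = list(feature_names)
        self.sample_ids = list(sample_ids)
        self.n_reads = 0

    @property
    def matrix(self) -> np.ndarray:
        self.n_reads += 1
        return self._matrix

    @property
    def n_samples(self) -> int:
        return self._matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self._matrix.shape[1]

    def restrict_features(self, indices: Sequence[int]) -> "Dataset":
        """New Dataset keeping only the given feature columns (read-counted)."""
        idx = np.asarray(list(indices), dtype=int)
        return Dataset(
            self.matrix[:, idx],
            self.labels.copy(),
            [self.feature_names[j] for j in idx],
            list(self.sample_ids),
        )

    def restrict_samples(self, rows: Sequence[int]) -> "Dataset":
        """New Dataset keeping only the given sample rows (read-counted)."""
        rows = np.asarray(list(rows), dtype=int)
        return Dataset(
            self.matrix[rows],
            self.labels[rows],
            list(self.feature_names),
            [self.sample_ids[i] for i in rows],
        )

    def equals(self, other: "Dataset") -> bool:
        return (
            np.allclose(self._matrix, other._matrix)
            and np.array_equal(self.labels, other.labels)
            and self.feature_names == other.feature_names
            and self.sample_ids == other.sample_ids
        )


@dataclass(frozen=True)
class FoldPlan:
    """Stratified k-fold assignment: per-sample fold index in [0, k)."""

    k: int
    assignment: np.ndarray

    def test_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass
class RunConfig:
    """Optimizer and pipeline settings.

    Defaults follow the scaled desk profile; :meth:`paper_profile` gives the
    full-scale published settings (filter NP=100/Na=200/Ite=10000, wrapper
    NP=50/Na=100/Ite=400).
    """

    stage: str = "two-stage"  # filter | wrapper | two-stage
    NP: int = 30
    Na: int = 60
    Ite: int = 500
    lam: float = 0.5  # binarization threshold, in (0,1)
    alpha: float = 0.2  # DE2 trade-off between subset size and error
    knn_k: int = 3
    seed: int = 0
    output_dir: str | None = None
    # stage-specific overrides used by the two-stage pipeline
    filter_NP: int = 30
    filter_Na: int = 60
    filter_Ite: int = 500
    filter_lam: float | None = None  # None -> dimension-dependent default
    wrapper_NP: int = 30
    wrapper_Na: int = 60
    wrapper_Ite: int = 200
    wrapper_lam: float = 0.5
    inner_folds: int = 5
    zscore: bool = False

    def __post_init__(self):
        if self.NP < 4:
            raise ValueError("NP must be >= 4 (mutation needs 3 distinct non-target indices)")
        if self.Na < 1 or self.Ite < 1:
            raise ValueError("Na and Ite must be >= 1")
        if not (0.0 < self.lam < 1.0):
            raise ValueError("lambda must lie in (0,1)")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0,1]")

    @classmethod
    def paper_profile(cls, **kw) -> "RunConfig":
        base = dict(
            NP=100, Na=200, Ite=10_000,
            filter_NP=100, filter_Na=200, filter_Ite=10_000,
            wrapper_NP=50, wrapper_Na=100, wrapper_Ite=400,
        )
        base.update(kw)
        return cls(**base)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def default_filter_lambda(n_features: int, target_size: int = 200) -> float:
    """Dimension-dependent filter-stage threshold.

    Chosen so a uniform-random position initially selects roughly
    ``min(target_size, M/10)`` features; clamped to [0.5, 0.99].
    """
    m = max(n_features, 1)
    want = min(target_size, max(m // 10, 1))
    lam = 1.0 - want / m
    return float(np.clip(lam, 0.5, 0.99))


def load_dataset(path, label_column: str, fmt: str | None = None,
                 transpose: bool = False) -> Dataset:
    """Read a labeled expression matrix from CSV/TSV/ARFF.

    Samples in rows, genes in columns, one label column (``transpose=True``
    for gene-in-rows files).  The two observed label values are mapped to
    {0,1} in sorted order.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".arff": "arff"}.get(path.suffix.lower(), "csv")
    if fmt == "arff":
        from scipy.io import arff as scipy_arff

        data, _meta = scipy_arff.loadarff(path)
        df = pd.DataFrame(data)
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
    else:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if transpose:
            df = df.T
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    raw_labels = df[label_column].astype(str)
    values = sorted(raw_labels.unique())
    if len(values) != 2:
        raise ValueError("not a binary problem")
    labels = raw_labels.map({values[0]: 0, values[1]: 1}).to_numpy()
    feats = df.drop(columns=[label_column])
    try:
        mat = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = next(
            (r, c)
            for r in range(feats.shape[0])
            for c, col in enumerate(feats.columns)
            if not _is_number(feats.iloc[r, c])
        )
        raise ValueError(
            f"non-numeric feature cell at row {bad[0]}, column {feats.columns[bad[1]]!r}"
        ) from exc
    if np.isnan(mat).any():
        raise ValueError("missing values in matrix are rejected")
    return Dataset(mat, labels, list(feats.columns), [str(i) for i in df.index])


def _is_number(v) -> bool:
    try:
        float(v)
        return not np.isnan(float(v))
    except (TypeError, ValueError):
        return False


def write_dataset(ds: Dataset, path, fmt: str = "csv",
                  label_column: str = "class") -> None:
    """Write a Dataset so that :func:`load_dataset` reads it back unchanged."""
    if ds.n_features == 0:
        raise ValueError("no features")
    sep = "\t" if fmt == "tsv" else ","
    df = pd.DataFrame(ds._matrix, columns=ds.feature_names,
                      index=pd.Index(ds.sample_ids, name="sample"))
    df[label_column] = ds.labels
    df.to_csv(path, sep=sep)


def stratified_kfold(labels, k: int, seed: int) -> FoldPlan:
    """Stratified k-fold split of binary labels, deterministic per seed."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels.astype(int))
    if (counts[counts > 0] < k).any():
        raise ValueError("insufficient class size for the requested fold count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_tr, te) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[te] = fold
    return FoldPlan(k=k, assignment=assignment)
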