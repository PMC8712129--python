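"""Objective functions for both selection stages.

A continuous position vector in [0,1]^M is decoded into a feature subset by
thresholding at lambda.  The filter stage scores a subset by three
criteria: its size, its mean relevance to the class (mean mutual
information I(s_i; c), negated for minimization), and its mean pairwise
redundancy (mean I(s_i; s_j) over ordered pairs i != j, divided by |S|^2).
The wrapper stage scores a subset by its size and the 5-fold
cross-validated error rate of a Gaussian naive Bayes classifier.  DE1 and
DE2 are the scalarized baselines: error rate alone, and the
alpha-weighted combination of normalized size and error rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.naive_bayes import GaussianNB

from .io_data import Dataset, FoldPlan
from .info_theory import MICache

__all__ = [
    "FeatureSubset",
    "NBModel",
    "binarize",
    "filter_objectives",
    "nb_fit",
    "nb_predict",
    "cv_error",
    "wrapper_objectives",
    "de1_fitness",
    "de2_fitness",
]


@dataclass(frozen=True)
class FeatureSubset:
    """Strictly increasing feature indices into an M-dimensional space."""

    indices: tuple[int, ...]
    source_dim: int

    def __post_init__(self):
        idx = self.indices
        if len(idx) == 0:
            raise ValueError("feature subset must be nonempty")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("indices must be strictly increasing")
        if idx[0] < 0 or idx[-1] >= self.source_dim:
            raise ValueError("index out of range")

    def __len__(self) -> int:
        return len(self.indices)

    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


def binarize(position: np.ndarray, lam: float) -> FeatureSubset:
    """Decode a position into a subset: feature j selected iff position_j >= lambda.

    An empty decode is repaired by selecting the single feature with the
    largest component, so every individual stays evaluable.
    """
    if not (0.0 < lam < 1.0):
        raise ValueError("lambda must lie in (0,1)")
    position = np.asarray(position, dtype=float)
    sel = np.flatnonzero(position >= lam)
    if sel.size == 0:
        sel = np.array([int(np.argmax(position))])
    return FeatureSubset(tuple(int(j) for j in sel), len(position))


def filter_objectives(S: FeatureSubset, cache: MICache) -> np.ndarray:
    """(f1, f2, f3) = (|S|, -mean relevance, mean pairwise redundancy).

    f2 = -(1/|S|) sum I(s_i; c); f3 = (1/|S|^2) sum over ordered pairs
    i != j of I(s_i; s_j) (self-pairs excluded; the divisor stays |S|^2).
    """
    if S.source_dim != cache.n_features:
        raise ValueError("subset and cache refer to different feature spaces")
    idx = S.array()
    n = len(idx)
    f1 = float(n)
    f2 = -float(cache.relevance[idx].mean())
    if n == 1:
        f3 = 0.0
    else:
        sub = cache.redundancy_submatrix(idx)
        f3 = float(sub.sum()) / (n * n)  # diagonal is zero (self-pairs excluded)
    return np.array([f1, f2, f3])


@dataclass
class NBModel:
    """Gaussian naive Bayes: per-class priors and per-feature Gaussians."""

    clf: GaussianNB
    n_features: int

    @property
    def priors(self) -> np.ndarray:
        return self.clf.class_prior_

    @property
    def means(self) -> np.ndarray:
        return self.clf.theta_

    @property
    def variances(self) -> np.ndarray:
        return self.clf.var_


def nb_fit(X: np.ndarray, y: np.ndarray) -> NBModel:
    """Maximum-likelihood Gaussian NB fit.

    Per-class feature means and (biased) variances; variances are smoothed
    by 1e-9 x the largest feature variance so constant features stay
    evaluable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    if (counts < 2).any():
        raise ValueError("need at least 2 samples per class")
    clf = GaussianNB()
    clf.fit(X, y)
    return NBModel(clf=clf, n_features=X.shape[1])


def nb_predict(model: NBModel, x: np.ndarray) -> int | np.ndarray:
    """Class with the largest log posterior; exact ties go to class 0.

    Accepts a single sample vector or a samples x features matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim <= 1
    X = np.atleast_2d(x.astype(float))
    if X.shape[1] != model.n_features:
        raise ValueError("dimension mismatch with the fitted model")
    pred = model.clf.predict(X)  # argmax breaks exact ties toward class 0
    return int(pred[0]) if single else pred


def cv_error(ds: Dataset, folds: FoldPlan) -> float:
    """Mean over folds of the per-fold NB misclassification rate."""
    if len(folds.assignment) != ds.n_samples:
        raise ValueError("fold plan does not match the dataset")
    X = ds.matrix
    y = ds.labels
    errs = []
    for f in range(folds.k):
        tr = folds.train_rows(f)
        te = folds.test_rows(f)
        if len(np.unique(y[tr])) < 2:
            raise ValueError("single-class training split")
        model = nb_fit(X[tr], y[tr])
        pred = nb_predict(model, X[te])
        errs.append(float(np.mean(pred != y[te])))
    return float(np.mean(errs))


def wrapper_objectives(position: np.ndarray, lam: float, ds: Dataset,
                       folds: FoldPlan) -> np.ndarray:
    """(f1, f2) = (number of selected features, inner-CV NB error rate)."""
    S = binarize(position, lam)
    reduced = ds.restrict_features(S.indices)
    return np.array([float(len(S)), cv_error(reduced, folds)])


def de1_fitness(position: np.ndarray, lam: float, ds: Dataset,
                folds: FoldPlan) -> float:
    """Baseline DE1: cross-validated error rate only."""
    S = binarize(position, lam)
    return cv_error(ds.restrict_features(S.indices), folds)


def de2_fitness(position: np.ndarray, lam: float, ds: Dataset,
                folds: FoldPlan, alpha: float) -> float:
    """Baseline DE2: alpha |S|/M + (1 - alpha) ErrorRate."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0,1]")
    S = binarize(position, lam)
    err = cv_error(ds.restrict_features(S.indices), folds)
    return alpha * (len(S) / S.source_dim) + (1.0 - alpha) * err
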