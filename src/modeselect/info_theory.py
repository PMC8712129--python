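"""Entropy and mutual-information estimation.

Discrete variables use the plug-in estimator from empirical frequencies.
Continuous-continuous MI uses the Kraskov-Stoegbauer-Grassberger (KSG)
k-nearest-neighbor estimator, variant 1, under the Chebyshev (max-norm)
metric.  Continuous-discrete MI (feature vs. binary class) uses the
class-conditional neighbor-counting analogue.  All values are in nats and
negative estimates are clipped to zero, so downstream redundancy sums stay
nonnegative.

Ties in neighbor distances break KNN estimators, so continuous inputs
receive a deterministic uniform jitter of amplitude 1e-10 x the sample
standard deviation.  The jitter stream is derived from the run seed and the
array contents, which makes every estimate reproducible and makes
``mi_knn_cc(x, y) == mi_knn_cc(y, x)`` hold to floating-point accuracy.
"""

from __future__ import annotations

import warnings
import zlib

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

__all__ = [
    "entropy_discrete",
    "mi_discrete",
    "mi_knn_cc",
    "mi_cd",
    "MICache",
    "build_cache",
]

_JITTER_SCALE = 1e-10


def entropy_discrete(x) -> float:
    """Plug-in Shannon entropy of a discrete sequence, in nats."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("entropy of an empty sequence is undefined")
    _, counts = np.unique(x, return_counts=True)
    p = np.sort(counts / counts.sum())  # fixed summation order: exact symmetry
    return float(-(p * np.log(p)).sum())


def mi_discrete(x, y) -> float:
    """Plug-in mutual information H(x) + H(y) - H(x,y) of two discrete sequences."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    # joint symbols via pairing of factorized codes
    xc = np.unique(x, return_inverse=True)[1]
    yc = np.unique(y, return_inverse=True)[1]
    joint = xc * (yc.max() + 1) + yc
    return entropy_discrete(x) + entropy_discrete(y) - entropy_discrete(joint)


def _jitter(x: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic tie-breaking jitter, keyed on the array contents and seed."""
    sd = float(np.std(x))
    if sd == 0.0:
        return x
    key = (zlib.crc32(np.ascontiguousarray(x, dtype=float).tobytes()) ^ (seed & 0xFFFFFFFF)) % (2**31)
    rng = np.random.default_rng(key)
    return x + rng.uniform(-1.0, 1.0, size=x.shape) * (_JITTER_SCALE * sd)


def mi_knn_cc(x, y, k: int = 3, seed: int = 0) -> float:
    """KSG (variant 1) mutual information between two continuous sequences.

    Chebyshev metric; nats; clipped below at 0.  A constant input has no
    information content and returns 0 with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("sequences must have equal length")
    if n <= k:
        raise ValueError("need more samples than neighbors (n > k)")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("constant input to mi_knn_cc; returning 0", stacklevel=2)
        return 0.0
    x = _jitter(x, seed)
    y = _jitter(y, seed)
    tree = cKDTree(np.column_stack([x, y]))
    # distance to the k-th neighbor in the joint space (excluding self)
    eps = tree.query(np.column_stack([x, y]), k=k + 1, p=np.inf)[0][:, -1]
    nx = _count_within(x, eps)
    ny = _count_within(y, eps)
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return float(max(mi, 0.0))


def _count_within(v: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Per point: how many other points lie strictly within eps on this axis."""
    order = np.argsort(v)
    sv = v[order]
    hi = np.searchsorted(sv, v + eps, side="left")
    lo = np.searchsorted(sv, v - eps, side="right")
    return hi - lo - 1  # exclude the point itself


def mi_cd(x, c, k: int = 3, seed: int = 0) -> float:
    """Mutual information between a continuous feature and a binary class.

    Class-conditional KNN estimator: for each sample, the radius is the
    distance to its k-th nearest neighbor within its own class; the count of
    samples from the full pool inside that radius calibrates the estimate.
    Nats, clipped below at 0, bounded above (up to estimator noise) by H(c).
    """
    x = np.asarray(x, dtype=float).ravel()
    c = np.asarray(c).ravel()
    n = x.size
    if c.size != n:
        raise ValueError("sequences must have equal length")
    classes, counts = np.unique(c, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if (counts <= k).any():
        raise ValueError("every class must have more than k members")
    if np.std(x) == 0.0:
        warnings.warn("constant input to mi_cd; returning 0", stacklevel=2)
        return 0.0
    x = _jitter(x, seed)
    radius = np.empty(n)
    label_counts = np.empty(n)
    for cls, cnt in zip(classes, counts):
        mask = c == cls
        xv = x[mask]
        d = np.abs(xv[:, None] - xv[None, :])
        np.fill_diagonal(d, np.inf)
        radius[mask] = np.partition(d, k - 1, axis=1)[:, k - 1]
        label_counts[mask] = cnt
    # m: points of the full pool strictly inside the class radius (incl. self)
    d_all = np.abs(x[:, None] - x[None, :])
    m = (d_all < radius[:, None]).sum(axis=1)
    mi = digamma(n) + digamma(k) - np.mean(digamma(label_counts)) - np.mean(digamma(m))
    return float(max(mi, 0.0))


def _ksg_pairs_batch(X: np.ndarray, pairs: np.ndarray, k: int,
                     chunk: int = 256) -> np.ndarray:
    """Vectorized KSG MI for many feature pairs of a small-n matrix.

    ``X`` is samples x features (already jittered), ``pairs`` an array of
    (i, j) column index pairs.  Equivalent to calling the single-pair
    estimator per pair, but broadcasts the n x n Chebyshev distance
    computation over chunks of pairs; this is what makes redundancy
    evaluation over tens of thousands of gene pairs tractable.
    """
    n = X.shape[0]
    out = np.empty(len(pairs))
    const = digamma(k) + digamma(n)
    for start in range(0, len(pairs), chunk):
        pp = pairs[start:start + chunk]
        a = X[:, pp[:, 0]].T  # (P, n)
        b = X[:, pp[:, 1]].T
        dx = np.abs(a[:, :, None] - a[:, None, :])
        dy = np.abs(b[:, :, None] - b[:, None, :])
        dz = np.maximum(dx, dy)
        idx = np.arange(n)
        dz[:, idx, idx] = np.inf
        eps = np.partition(dz, k - 1, axis=2)[:, :, k - 1]  # (P, n)
        nx = (dx < eps[:, :, None]).sum(axis=2) - 1  # diagonal dx=0 counts self
        ny = (dy < eps[:, :, None]).sum(axis=2) - 1
        mi = const - np.mean(digamma(nx + 1) + digamma(ny + 1), axis=1)
        out[start:start + chunk] = mi
    return np.maximum(out, 0.0)


class MICache:
    """Per-feature relevance I(s_i; c) and lazy pairwise redundancy I(s_i; s_j).

    Relevance is computed eagerly at construction.  Redundancy entries are
    computed on first request (in vectorized batches when a whole subset is
    queried) and memoized in a dense symmetric matrix.
    """

    def __init__(self, ds, knn_k: int = 3, seed: int = 0):
        self.knn_k = int(knn_k)
        self.seed = int(seed)
        self.n_features = ds.n_features
        raw = ds.matrix
        labels = ds.labels
        # jitter each column once; all pairwise estimates reuse the same
        # jittered values, making redundancy symmetric by construction
        self._X = np.column_stack(
            [_jitter(raw[:, j], self.seed + j) for j in range(self.n_features)]
        )
        self.relevance = np.array(
            [self._relevance_one(self._X[:, j], labels) for j in range(self.n_features)]
        )
        self._red = np.zeros((self.n_features, self.n_features))
        self._have = np.zeros((self.n_features, self.n_features), dtype=bool)
        np.fill_diagonal(self._have, True)  # self-pairs never used
        self.pairs_computed = 0

    def _relevance_one(self, x: np.ndarray, labels: np.ndarray) -> float:
        if np.std(x) == 0.0:
            return 0.0
        return mi_cd(x, labels, k=self.knn_k, seed=self.seed)

    @property
    def n_redundancy_entries(self) -> int:
        return self.pairs_computed

    def redundancy(self, i: int, j: int) -> float:
        """I(s_i; s_j) for one unordered pair, memoized."""
        if i == j:
            raise ValueError("self-pairs are excluded from redundancy")
        if not self._have[i, j]:
            self._compute_pairs(np.array([[min(i, j), max(i, j)]]))
        return float(self._red[i, j])

    def redundancy_submatrix(self, indices) -> np.ndarray:
        """Symmetric redundancy matrix over a feature subset (computed as needed)."""
        idx = np.asarray(list(indices), dtype=int)
        sub_have = self._have[np.ix_(idx, idx)]
        if not sub_have.all():
            ti, tj = np.triu_indices(len(idx), k=1)
            need = ~sub_have[ti, tj]
            missing = np.column_stack([idx[ti[need]], idx[tj[need]]])
            missing = np.unique(np.sort(missing, axis=1), axis=0)
            self._compute_pairs(missing)
        return self._red[np.ix_(idx, idx)]

    def _compute_pairs(self, pairs: np.ndarray) -> None:
        if len(pairs) == 0:
            return
        # features with zero variance carry no information
        sd = self._X.std(axis=0)
        ok = (sd[pairs[:, 0]] > 0) & (sd[pairs[:, 1]] > 0)
        vals = np.zeros(len(pairs))
        if ok.any():
            vals[ok] = _ksg_pairs_batch(self._X, pairs[ok], self.knn_k)
        i, j = pairs[:, 0], pairs[:, 1]
        self._red[i, j] = vals
        self._red[j, i] = vals
        self._have[i, j] = True
        self._have[j, i] = True
        self.pairs_computed += len(pairs)


def build_cache(ds, k: int = 3, seed: int = 0) -> MICache:
    """Build the relevance/redundancy cache for a dataset."""
    return MICache(ds, knn_k=k, seed=seed)
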