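"""Synthetic microarray-like datasets with planted statistical structure.

The generator emulates the small-n / large-p regime of two-class
expression studies (tens of samples, thousands of genes): a handful of
informative genes whose class-conditional means differ by ``effect``
standard deviations, redundant genes correlated with those informative
parents, and a large block of class-independent noise genes.  Because the
informative genes are class-conditionally Gaussian and independent, the
Bayes error of an m-gene informative subset is known in closed form
(Phi(-effect * sqrt(m) / 2)), which anchors what a wrapper stage can
achieve on this data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_data import Dataset

__all__ = ["SynthSpec", "make_dataset", "make_exact_fixture", "bayes_error"]


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings.

    effect: class-mean separation delta in units of the feature standard
    deviation; rho: correlation of each redundant copy with its informative
    parent; class_balance: probability of class 1.
    """

    n_samples: int = 60
    n_informative: int = 5
    n_redundant: int = 20
    n_noise: int = 475
    effect: float = 2.0
    rho: float = 0.9
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.n_informative < 0 or self.n_redundant < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.n_informative + self.n_redundant + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if self.n_redundant > 0 and self.n_informative < 1:
            raise ValueError("redundant features need informative parents")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie in (0,1)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0,1)")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def make_dataset(spec: SynthSpec) -> tuple[Dataset, np.ndarray]:
    """Generate a Dataset plus the ground-truth informative index set.

    Feature layout: informative genes first (class-conditional
    N(-delta/2, 1) / N(+delta/2, 1)), then redundant copies
    rho * parent + sqrt(1 - rho^2) * noise with parents cycled over the
    informative block, then independent N(0, 1) noise genes.  Labels are
    Bernoulli(class_balance), redrawn until both classes have at least two
    members.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_features
    while True:
        labels = (rng.uniform(size=n) < spec.class_balance).astype(int)
        if 2 <= labels.sum() <= n - 2:
            break
    X = np.empty((n, m))
    shift = spec.effect / 2.0
    for j in range(spec.n_informative):
        X[:, j] = rng.normal(size=n) + np.where(labels == 1, shift, -shift)
    for r in range(spec.n_redundant):
        parent = r % spec.n_informative
        j = spec.n_informative + r
        X[:, j] = spec.rho * X[:, parent] + np.sqrt(1 - spec.rho**2) * rng.normal(size=n)
    for j in range(spec.n_informative + spec.n_redundant, m):
        X[:, j] = rng.normal(size=n)
    names = (
        [f"inf{j}" for j in range(spec.n_informative)]
        + [f"red{r}" for r in range(spec.n_redundant)]
        + [f"noise{j}" for j in range(spec.n_noise)]
    )
    ds = Dataset(X, labels, names)
    return ds, np.arange(spec.n_informative)


def bayes_error(effect: float, m_informative: int) -> float:
    """Bayes error of an m-gene independent informative subset: Phi(-delta sqrt(m)/2)."""
    from scipy.stats import norm

    return float(norm.cdf(-effect * np.sqrt(m_informative) / 2.0))


def make_exact_fixture() -> Dataset:
    """8 samples x 3 features with hand-checkable statistics.

    Feature 0 separates the classes exactly (class 0: {1, 2, 3, 4},
    class 1: {11, 12, 13, 14}); after median binarization it matches the
    class perfectly, so its discrete MI with the class is ln 2.  Feature 1
    carries no class signal; feature 2 is constant (zero entropy, zero MI).
    """
    X = np.array(
        [
            [1.0, 5.0, 7.0],
            [2.0, -3.0, 7.0],
            [3.0, 4.0, 7.0],
            [4.0, -2.0, 7.0],
            [11.0, 6.0, 7.0],
            [12.0, -4.0, 7.0],
            [13.0, 3.0, 7.0],
            [14.0, -1.0, 7.0],
        ]
    )
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    return Dataset(X, labels, ["sep", "scatter", "flat"])
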