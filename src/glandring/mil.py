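"""Bags of lumen instances and bag dissimilarity.

An image is a "bag" of proximity-feature instances, one per lumen region;
only the bag carries a grade label. The distance between two bags is the
linear assignment distance: an optimal one-to-one matching of the smaller
bag's instances onto distinct instances of the larger bag minimizing total
instance distance, reported as the mean matched distance. The N x N bag
dissimilarity matrix becomes an ordinary feature space, decoupling the
multiple-instance formulation from the choice of classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


@dataclass
class Bag:
    """One image's instance collection.

    ``instances`` is an (n_instances, n_features) array; every bag in a
    dataset shares the feature dimensionality. ``label`` is the image
    grade (e.g. "C0"/"C1") or None when unknown.
    """

    bag_id: str
    instances: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.instances = np.atleast_2d(np.asarray(self.instances, dtype=np.float64))
        if self.instances.shape[0] < 1:
            raise ValueError(f"bag {self.bag_id!r} has no instances")
        if not np.all(np.isfinite(self.instances)):
            raise ValueError(f"bag {self.bag_id!r} has non-finite instances")

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    @property
    def n_features(self) -> int:
        return self.instances.shape[1]


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative inter-bag distances with zero diagonal."""

    values: np.ndarray
    bag_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square")
        if not self.bag_ids:
            self.bag_ids = [str(i) for i in range(n)]


def instance_distance(a: np.ndarray, b: np.ndarray, metric: str = "euclidean") -> float:
    """Distance between two instance vectors (euclidean or cityblock)."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "cityblock":
        return float(np.abs(a - b).sum())
    raise ValueError(f"unknown metric {metric!r}")


def bag_distance(A: Bag, B: Bag, metric: str = "euclidean") -> float:
    """Linear assignment distance between two bags.

    Instances of the smaller bag are matched one-to-one onto distinct
    instances of the larger bag so that the summed instance distance is
    minimal (rectangular assignment); the value returned is the mean over
    the matched pairs. Surplus instances of the larger bag are ignored,
    so the measure does not penalize instance-rich images for size alone.
    Symmetric by construction.
    """
    if A.n_features != B.n_features:
        raise ValueError("bags have different instance dimensionality")
    cost = cdist(A.instances, B.instances, metric=metric)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def dissimilarity_matrix(
    bags: list[Bag], metric: str = "euclidean"
) -> DissimilarityMatrix:
    """Pairwise bag distances; row i is bag i's dissimilarity-space vector."""
    if len(bags) < 2:
        raise ValueError("need at least 2 bags")
    n = len(bags)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bag_distance(bags[i], bags[j], metric=metric)
    return DissimilarityMatrix(D, [b.bag_id for b in bags])


def standardize_bags(bags: list[Bag]) -> list[Bag]:
    """Z-score instance features over all bags' instances pooled.

    Needed when instance features mix scales (the scalar shape baseline
    mixes a pixel count with three O(1) ratios); proximity features are
    already fractions and do not require it. Constant features are left
    centered at zero.
    """
    pooled = np.concatenate([b.instances for b in bags])
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)
    std[std == 0] = 1.0
    return [
        Bag(b.bag_id, (b.instances - mean) / std, label=b.label) for b in bags
    ]


def cross_distances(
    bags_a: list[Bag], bags_b: list[Bag], metric: str = "euclidean"
) -> np.ndarray:
    """Rectangular bag-distance matrix between two bag lists.

    Used to embed held-out bags into the dissimilarity space spanned by
    training bags without computing test-to-test distances.
    """
    out = np.empty((len(bags_a), len(bags_b)))
    for i, a in enumerate(bags_a):
        for j, b in enumerate(bags_b):
            out[i, j] = bag_distance(a, b, metric=metric)
    return out
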