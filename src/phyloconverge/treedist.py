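"""Tree incongruence: partition metric and principal coordinates embedding.

The partition (Robinson–Foulds / symmetric difference) metric between two
trees on the same tips is the number of non-trivial unrooted bipartitions
present in exactly one of them.  Unresolved nodes simply contribute fewer
splits; a split missing for lack of resolution counts as present in one tree
only (no partial credit).

Classical scaling (PCoA) embeds a set of trees from their pairwise
distances: square the distances, double-center (Gower), eigendecompose, and
scale eigenvectors by the square root of their eigenvalues.  Negative
eigenvalues — possible because the partition metric need not be Euclidean —
are reported but excluded from coordinates and from the percent-variance
denominator; no Cailliez/Lingoes correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .treeio import PhyloTree, bipartitions

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "rf_distance",
    "distance_matrix",
    "pcoa",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # (n_items, n_positive_axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # per positive axis, sums to 100
    negative_eigenvalue_flag: bool
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count of non-trivial unrooted splits."""
    s1, s2 = set(t1.tip_labels), set(t2.tip_labels)
    if s1 != s2:
        only1, only2 = sorted(s1 - s2), sorted(s2 - s1)
        raise ValueError(
            f"tip sets differ: only in first {only1}, only in second {only2}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def distance_matrix(trees, labels=None) -> DistanceMatrix:
    trees = list(trees)
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    if labels is None:
        labels = [f"tree{i + 1}" for i in range(len(trees))]
    splits = [bipartitions(t) for t in trees]
    tipset = set(trees[0].tip_labels)
    for t in trees[1:]:
        if set(t.tip_labels) != tipset:
            rf_distance(trees[0], t)  # raises with the asymmetric labels
    n = len(trees)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = len(splits[i] ^ splits[j])
    return DistanceMatrix(labels=list(labels), values=d)


def pcoa(dm: DistanceMatrix, eps: float = 1e-9) -> PCoAResult:
    """Classical scaling of a distance matrix.

    Axis signs are made reproducible by forcing the largest-magnitude
    loading on each axis to be positive.  Eigenvalues within ``eps`` of zero
    (relative to the largest) are treated as zero.
    """
    d = dm.values
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = eps * max(abs(vals[0]), 1.0)
    vals = np.where(np.abs(vals) < tol, 0.0, vals)
    pos = vals > 0
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = vals[pos].sum()
    pct = 100.0 * vals[pos] / pos_sum if pos_sum > 0 else vals[pos]
    return PCoAResult(
        coordinates=coords,
        eigenvalues=vals,
        percent_variance=pct,
        negative_eigenvalue_flag=bool(np.any(vals < 0)),
        labels=list(dm.labels),
    )
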