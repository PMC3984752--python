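"""Fuzzy partitioning of numerical features.

Each numerical feature is discretised into linguistic terms by hierarchical
agglomerative clustering of its observed values: clustering starts from
singleton clusters and repeatedly merges the closest pair under the
average-pairwise absolute difference

    d(c1, c2) = (1 / |c1||c2|) * sum_{x in c1} sum_{y in c2} |x - y|

until the smallest inter-cluster distance exceeds a threshold ``epsilon``.
The surviving cluster centroids become the midpoints of a triangular fuzzy
partition over [min, max]: one left semi-trapezoid, one triangle per interior
midpoint, and one right semi-trapezoid.  The membership functions form a
partition of unity on the observed domain.

For one-dimensional data the average-linkage distance between two clusters
that occupy disjoint value ranges collapses to the difference of their
centroids, and the globally closest pair is always adjacent in sorted order;
:func:`agglomerate` exploits this, merging only sorted-adjacent clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import Dataset

#: Linguistic vocabularies assigned to partitions by fuzzy-set count;
#: partitions with more sets fall back to generated "set_<j>" names.
DEFAULT_LABELS: dict[int, list[str]] = {
    2: ["low", "high"],
    3: ["low", "medium", "high"],
    4: ["low", "low-medium", "high-medium", "high"],
    5: ["very low", "low", "medium", "high", "very high"],
}

#: Fraction of the observed range used as the default merge threshold.
DEFAULT_EPSILON_FRACTION = 0.15

#: Hard cap on fuzzy sets per feature; merging continues past epsilon if
#: exceeded.
MAX_FUZZY_SETS = 5


class DegeneratePartitionError(ValueError):
    """All observed values identical: treat the feature as categorical."""


@dataclass
class Cluster:
    """A non-empty multiset of observed values of one feature."""

    members: list[float]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty cluster")
        self.members = [float(v) for v in self.members]

    @property
    def centroid(self) -> float:
        return float(np.mean(self.members))

    def __len__(self) -> int:
        return len(self.members)


def cluster_distance(c1: Cluster, c2: Cluster) -> float:
    """Average pairwise absolute difference between two clusters.

    Symmetric, non-negative, and zero exactly when every cross-pair of
    members is equal.
    """
    a = np.asarray(c1.members, dtype=float)
    b = np.asarray(c2.members, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty cluster")
    return float(np.abs(a[:, None] - b[None, :]).mean())


def agglomerate(values: Iterable[float], epsilon: float) -> list[Cluster]:
    """Average-linkage agglomerative clustering of 1-D values.

    Starts from singletons (in sorted order), repeatedly merges the pair of
    clusters with the smallest average-linkage distance, and stops once the
    smallest distance exceeds ``epsilon`` (or one cluster remains).  Ties are
    broken toward the pair whose left cluster has the lower centroid, then by
    list order.  Returns clusters sorted by centroid.
    """
    vals = sorted(float(v) for v in values)
    if not vals:
        raise ValueError("agglomerate requires at least one value")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    # Clusters are contiguous blocks of the sorted values, so the closest
    # pair is always adjacent and its distance is the centroid gap; track
    # (start, count, sum) per block to keep each merge O(n).
    blocks = [(i, 1, v) for i, v in enumerate(vals)]
    while len(blocks) > 1:
        cents = [s / c for (_, c, s) in blocks]
        gaps = [b - a for a, b in zip(cents, cents[1:])]
        i = int(np.argmin(gaps))
        if gaps[i] > epsilon:
            break
        s0, c0, v0 = blocks[i]
        _, c1, v1 = blocks[i + 1]
        blocks[i: i + 2] = [(s0, c0 + c1, v0 + v1)]
    return [Cluster(vals[s: s + c]) for (s, c, _) in blocks]


def _merge_to(clusters: list[Cluster], k: int) -> list[Cluster]:
    """Continue adjacent merges (ignoring epsilon) until at most k clusters."""
    clusters = list(clusters)
    while len(clusters) > k:
        gaps = [
            clusters[i + 1].centroid - clusters[i].centroid
            for i in range(len(clusters) - 1)
        ]
        i = int(np.argmin(gaps))
        clusters[i] = Cluster(clusters[i].members + clusters[i + 1].members)
        del clusters[i + 1]
    return clusters


@dataclass
class FuzzyPartition:
    """A triangular fuzzy partition of one numerical feature.

    ``m`` interior midpoints between the domain bounds induce ``m + 2`` fuzzy
    sets: a left semi-trapezoid anchored at the minimum, one triangle peaking
    at each midpoint, and a right semi-trapezoid anchored at the maximum.
    """

    feature: str
    v0: float
    midpoints: list[float]
    vmax: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.v0 = float(self.v0)
        self.vmax = float(self.vmax)
        self.midpoints = [float(v) for v in self.midpoints]
        knots = [self.v0, *self.midpoints, self.vmax]
        for a, b in zip(knots, knots[1:]):
            if not a < b:
                raise ValueError(
                    f"partition of {self.feature!r}: knots must be strictly "
                    f"increasing, got {knots}"
                )
        if not self.labels:
            n = self.n_sets
            self.labels = list(
                DEFAULT_LABELS.get(n, [f"set_{j}" for j in range(n)])
            )
        if len(self.labels) != self.n_sets:
            raise ValueError(
                f"partition of {self.feature!r}: {len(self.labels)} labels "
                f"for {self.n_sets} fuzzy sets"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"partition of {self.feature!r}: duplicate labels")

    @property
    def m(self) -> int:
        return len(self.midpoints)

    @property
    def n_sets(self) -> int:
        return self.m + 2

    @property
    def knots(self) -> list[float]:
        """Apex positions of the fuzzy sets: [v0, midpoints..., vmax]."""
        return [self.v0, *self.midpoints, self.vmax]

    def membership(self, j: int, x) -> float | np.ndarray:
        """Membership of ``x`` in fuzzy set ``j`` (0 = leftmost).

        The left set is 1 below the domain minimum and falls linearly to the
        first midpoint; interior sets are triangles peaking at their midpoint;
        the right set rises linearly from the last midpoint and is 1 above
        the domain maximum.
        """
        if not 0 <= j <= self.m + 1:
            raise IndexError(f"fuzzy-set index {j} out of range 0..{self.m + 1}")
        knots = np.asarray(self.knots)
        apex = np.zeros(len(knots))
        apex[j] = 1.0
        left = 1.0 if j == 0 else 0.0
        right = 1.0 if j == self.m + 1 else 0.0
        xs = np.asarray(x, dtype=float)
        out = np.interp(xs, knots, apex, left=left, right=right)
        return float(out) if np.isscalar(x) else out

    def membership_matrix(self, x) -> np.ndarray:
        """Memberships of values ``x`` in every set: shape (len(x), m + 2).

        Missing values (NaN) get zero membership in every set.
        """
        xs = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.column_stack([self.membership(j, xs) for j in range(self.n_sets)])
        out[np.isnan(xs), :] = 0.0
        return out

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "min": self.v0,
            "midpoints": list(self.midpoints),
            "max": self.vmax,
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzyPartition":
        return cls(d["feature"], d["min"], list(d["midpoints"]), d["max"],
                   list(d["labels"]))


def build_partition(
    feature: str,
    values: Iterable[float],
    epsilon: float | None = None,
    labels: Sequence[str] | None = None,
    max_sets: int = MAX_FUZZY_SETS,
) -> FuzzyPartition:
    """Cluster observed values and build the induced fuzzy partition.

    Cluster centroids become midpoints; centroids within a relative tolerance
    of a domain bound are dropped (they would create zero-width segments).
    ``epsilon`` defaults to ``0.15 *`` the observed range.  Raises
    :class:`DegeneratePartitionError` when all values are identical.
    """
    vals = sorted(float(v) for v in values)
    if not vals:
        raise ValueError(f"feature {feature!r}: no values to partition")
    v0, vmax = vals[0], vals[-1]
    if vmax - v0 <= 0:
        raise DegeneratePartitionError(
            f"feature {feature!r}: all values identical ({v0}); "
            "treat it as categorical"
        )
    rng = vmax - v0
    if epsilon is None:
        epsilon = DEFAULT_EPSILON_FRACTION * rng
    clusters = agglomerate(vals, epsilon)
    tol = 1e-9 * rng

    def interior(cs: list[Cluster]) -> list[float]:
        return [
            c.centroid
            for c in cs
            if c.centroid - v0 > tol and vmax - c.centroid > tol
        ]

    # Cap the set count by continuing merges past epsilon if needed.
    midpoints = interior(clusters)
    while len(midpoints) > max_sets - 2 and len(clusters) > 1:
        clusters = _merge_to(clusters, len(clusters) - 1)
        midpoints = interior(clusters)
    return FuzzyPartition(feature, v0, midpoints, vmax,
                          list(labels) if labels else [])


def partition_all(
    d: Dataset,
    epsilon: float | Mapping[str, float] | None = None,
    labels: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, FuzzyPartition]:
    """Build one fuzzy partition per numerical feature of a dataset.

    ``epsilon`` may be a single threshold applied to every feature or a
    per-feature mapping; omitted features use the range-fraction default.
    Categorical features are untouched.
    """
    partitions: dict[str, FuzzyPartition] = {}
    for feat in d.schema:
        if not feat.is_numerical:
            continue
        vals = d.numerical_values(feat.name)
        eps = epsilon.get(feat.name) if isinstance(epsilon, Mapping) else epsilon
        feat_labels = labels.get(feat.name) if labels else None
        try:
            partitions[feat.name] = build_partition(
                feat.name, vals, epsilon=eps, labels=feat_labels
            )
        except DegeneratePartitionError as exc:
            raise DegeneratePartitionError(
                f"feature {feat.name!r}: {exc}"
            ) from exc
    return partitions


def save_partitions(partitions: Mapping[str, FuzzyPartition], path) -> None:
    doc = [partitions[name].to_dict() for name in partitions]
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def load_partitions(path) -> dict[str, FuzzyPartition]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    parts = [FuzzyPartition.from_dict(entry) for entry in doc]
    return {p.feature: p for p in parts}
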