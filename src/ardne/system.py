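"""Neighborhood decision systems and granulation primitives.

A neighborhood decision system is a classification table: ``n`` samples
described by ``m`` real-valued conditional attributes plus one categorical
decision label, together with a neighborhood radius ``delta``.  Instead of
the equivalence classes of classical rough sets, continuous data is
granulated into *neighborhood classes*: all samples within Euclidean
distance ``delta`` of a sample, measured on a chosen attribute subset.
Lower/upper approximations of the decision partition and the approximate
precision are then defined exactly as in neighborhood rough set theory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "BOUNDARY_ATOL",
    "NeighborhoodDecisionSystem",
    "NeighborhoodIndex",
    "DecisionPartition",
    "ApproximationSummary",
    "load_decision_system",
    "normalize_min_max",
    "distance",
    "pairwise_distances",
    "neighborhoods",
    "decision_partition",
    "lower_approximation",
    "upper_approximation",
    "decision_approximations",
]

# Absolute tolerance on (distance - delta) at the neighborhood boundary.
# Membership is inclusive (distance <= delta); the tolerance keeps a
# sample whose distance equals delta exactly in real arithmetic from
# falling out through floating-point rounding.
BOUNDARY_ATOL = 1e-12


@dataclass(frozen=True)
class NeighborhoodDecisionSystem:
    """A (U, C, D, delta) decision table with continuous attributes.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_attributes)
        Real attribute matrix, one column per conditional attribute.
        Values are expected (not enforced) to live on comparable scales,
        typically [0, 1] after min-max normalization.
    decisions : ndarray of shape (n_samples,)
        Categorical decision label per sample.
    delta : float
        Neighborhood radius, 0 <= delta <= 1.
    attributes : tuple of str
        Attribute (column) names.
    samples : tuple of str
        Sample (row) identifiers.
    """

    values: np.ndarray
    decisions: np.ndarray
    delta: float
    attributes: tuple[str, ...] = ()
    samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x attributes)")
        n, m = values.shape
        if n < 1 or m < 1:
            raise ValueError("the system needs at least one sample and one attribute")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing or non-finite value at row {bad[0]}, column {bad[1]}"
            )
        decisions = np.asarray(self.decisions)
        if decisions.shape != (n,):
            raise ValueError("decisions must supply exactly one label per sample")
        if not 0.0 <= float(self.delta) <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        attributes = tuple(self.attributes) or tuple(f"a{k}" for k in range(m))
        samples = tuple(self.samples) or tuple(f"x{i}" for i in range(n))
        if len(attributes) != m:
            raise ValueError("attribute names do not match the matrix width")
        if len(samples) != n:
            raise ValueError("sample names do not match the matrix height")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "decisions", decisions)
        object.__setattr__(self, "delta", float(self.delta))
        object.__setattr__(self, "attributes", attributes)
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def with_delta(self, delta: float) -> "NeighborhoodDecisionSystem":
        """Return a copy of the system with a different radius."""
        return dataclasses.replace(self, delta=delta)

    def resolve_subset(self, subset: Iterable[int | str] | None) -> tuple[int, ...]:
        """Normalize an attribute subset to a sorted tuple of column indices.

        Accepts attribute names or 0-based indices; duplicates are
        rejected; ``None`` means the full attribute set.  The returned
        order is ascending, which fixes the deterministic iteration
        order used everywhere downstream.
        """
        if subset is None:
            return tuple(range(self.n_attributes))
        indices: list[int] = []
        for item in subset:
            if isinstance(item, str):
                try:
                    indices.append(self.attributes.index(item))
                except ValueError:
                    raise KeyError(f"unknown attribute name {item!r}") from None
            else:
                k = int(item)
                if not 0 <= k < self.n_attributes:
                    raise IndexError(f"attribute index {k} out of range")
                indices.append(k)
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate attributes in subset")
        return tuple(sorted(indices))


@dataclass(frozen=True)
class NeighborhoodIndex:
    """Per-sample neighborhood classes for one attribute subset.

    ``adjacency[i, j]`` is True iff sample ``j`` lies within distance
    ``delta`` of sample ``i`` on the subset.  The relation is reflexive
    and symmetric by construction.
    """

    subset: tuple[int, ...]
    delta: float
    adjacency: np.ndarray  # bool (n, n)

    @property
    def n_samples(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        """Sorted indices of the neighborhood class of sample ``i``."""
        return np.flatnonzero(self.adjacency[i])

    @property
    def sizes(self) -> np.ndarray:
        """Neighborhood cardinalities |n(x_i)| for every sample."""
        return self.adjacency.sum(axis=1)


@dataclass(frozen=True)
class DecisionPartition:
    """Equivalence partition of the universe induced by the decision."""

    labels: tuple  # distinct labels in order of first appearance
    class_of: np.ndarray  # int class index per sample
    classes: tuple[np.ndarray, ...] = field(default=())  # sample indices per class

    @property
    def class_sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.classes])

    def class_mask(self) -> np.ndarray:
        """Boolean matrix (n_classes, n_samples): membership indicator."""
        n = len(self.class_of)
        mask = np.zeros((len(self.classes), n), dtype=bool)
        for k, members in enumerate(self.classes):
            mask[k, members] = True
        return mask


@dataclass(frozen=True)
class ApproximationSummary:
    """Lower/upper approximation of the decision partition and precision.

    ``precision`` is |lower| / |upper|; because every sample belongs to
    its own neighborhood, the upper approximation of the decision
    partition is always the whole universe, so precision = |lower| / n.
    """

    lower: np.ndarray
    upper: np.ndarray
    precision: float


def load_decision_system(path: str | Path, delta: float) -> NeighborhoodDecisionSystem:
    """Read a decision table from CSV.

    The file must have a header row; every column except the last parses
    as a real conditional attribute and the last column is the
    categorical decision.  Raw values are kept as-is — use
    :func:`normalize_min_max` separately if the attributes are not on
    comparable scales.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError("CSV needs at least one attribute column and a decision column")
    if frame.shape[0] < 1:
        raise ValueError("CSV contains no data rows")
    cond = frame.iloc[:, :-1]
    for name in cond.columns:
        col = pd.to_numeric(cond[name], errors="coerce")
        if col.isna().any():
            row = int(col.index[col.isna()][0])
            raise ValueError(
                f"column {name!r} has a missing or non-numeric value at data row {row}"
            )
    values = cond.apply(pd.to_numeric).to_numpy(dtype=float)
    decisions = frame.iloc[:, -1].to_numpy()
    return NeighborhoodDecisionSystem(
        values=values,
        decisions=decisions,
        delta=delta,
        attributes=tuple(str(c) for c in cond.columns),
        samples=tuple(str(i) for i in frame.index),
    )


def normalize_min_max(system: NeighborhoodDecisionSystem) -> NeighborhoodDecisionSystem:
    """Rescale every attribute column to [0, 1] by (v - min) / (max - min).

    Constant columns map to all-zeros.  The decision column is untouched.
    """
    values = system.values
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    safe = np.where(span == 0.0, 1.0, span)
    scaled = (values - lo) / safe
    scaled[:, span == 0.0] = 0.0
    return dataclasses.replace(system, values=scaled)


def pairwise_distances(
    system: NeighborhoodDecisionSystem, subset: Iterable[int | str] | None = None
) -> np.ndarray:
    """Full Euclidean distance matrix on an attribute subset.

    The empty subset yields the all-zero matrix (zero attributes
    distinguish nothing), which makes every neighborhood the universe.
    """
    cols = system.resolve_subset(subset)
    n = system.n_samples
    if len(cols) == 0:
        return np.zeros((n, n))
    if n == 1:
        return np.zeros((1, 1))
    return squareform(pdist(system.values[:, cols], metric="euclidean"))


def distance(
    system: NeighborhoodDecisionSystem,
    subset: Iterable[int | str],
    i: int,
    j: int,
) -> float:
    """Euclidean distance between samples ``i`` and ``j`` on ``subset``."""
    cols = system.resolve_subset(subset)
    if len(cols) == 0:
        raise ValueError("distance requires a nonempty attribute subset")
    diff = system.values[i, cols] - system.values[j, cols]
    return float(np.sqrt(np.dot(diff, diff)))


def neighborhoods(
    system: NeighborhoodDecisionSystem,
    subset: Iterable[int | str] | None = None,
    delta: float | None = None,
) -> NeighborhoodIndex:
    """Neighborhood classes n(x) = {y : distance(x, y) <= delta} on a subset.

    The boundary is inclusive: a pair at distance exactly delta is
    mutually neighboring (compared with absolute tolerance
    ``BOUNDARY_ATOL`` to stabilize exact-boundary cases).  The empty
    subset gives n(x) = U for every x.
    """
    cols = system.resolve_subset(subset)
    d = system.delta if delta is None else float(delta)
    dist = pairwise_distances(system, cols)
    adjacency = dist <= d + BOUNDARY_ATOL
    return NeighborhoodIndex(subset=cols, delta=d, adjacency=adjacency)


def decision_partition(system: NeighborhoodDecisionSystem) -> DecisionPartition:
    """Group samples by decision label, classes ordered by first appearance."""
    labels: list = []
    class_of = np.empty(system.n_samples, dtype=int)
    for i, lab in enumerate(system.decisions):
        if lab not in labels:
            labels.append(lab)
        class_of[i] = labels.index(lab)
    classes = tuple(np.flatnonzero(class_of == k) for k in range(len(labels)))
    return DecisionPartition(labels=tuple(labels), class_of=class_of, classes=classes)


def _as_mask(target: Iterable[int] | np.ndarray, n: int) -> np.ndarray:
    target = np.asarray(list(target) if not isinstance(target, np.ndarray) else target)
    if target.dtype == bool:
        if target.shape != (n,):
            raise ValueError("boolean target mask has wrong length")
        return target
    mask = np.zeros(n, dtype=bool)
    if target.size:
        if target.min() < 0 or target.max() >= n:
            raise ValueError("target contains sample indices outside the universe")
        mask[target.astype(int)] = True
    return mask


def lower_approximation(index: NeighborhoodIndex, target) -> np.ndarray:
    """Samples whose entire neighborhood lies inside ``target``."""
    mask = _as_mask(target, index.n_samples)
    inside = ~(index.adjacency & ~mask).any(axis=1)
    return np.flatnonzero(inside)


def upper_approximation(index: NeighborhoodIndex, target) -> np.ndarray:
    """Samples whose neighborhood intersects ``target``."""
    mask = _as_mask(target, index.n_samples)
    touches = (index.adjacency & mask).any(axis=1)
    return np.flatnonzero(touches)


def decision_approximations(
    index: NeighborhoodIndex, partition: DecisionPartition
) -> ApproximationSummary:
    """Lower/upper approximation of the whole decision partition.

    Lower (upper) is the union over decision classes of the per-class
    lower (upper) approximations; precision is the ratio of their sizes.
    """
    n = index.n_samples
    lower_mask = np.zeros(n, dtype=bool)
    upper_mask = np.zeros(n, dtype=bool)
    for members in partition.classes:
        lower_mask[lower_approximation(index, members)] = True
        upper_mask[upper_approximation(index, members)] = True
    lower = np.flatnonzero(lower_mask)
    upper = np.flatnonzero(upper_mask)
    precision = len(lower) / len(upper) if len(upper) else 0.0
    return ApproximationSummary(lower=lower, upper=upper, precision=precision)
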