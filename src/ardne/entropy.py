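"""Neighborhood entropy measures on decision systems.

Four related uncertainty measures, all granulated by neighborhood
classes rather than equivalence classes:

* point neighborhood entropy of one sample, ``-log(|n(x)| / |U|)``;
* its plain average over the universe;
* the precision-weighted average, which multiplies the plain average by
  the approximate precision ``p_B(D)`` so that the algebra view (how
  completely the subset resolves the decision) and the information view
  (how finely it granulates the universe) are combined;
* the decision neighborhood entropy,

  ``H(D, B) = -(p_B(D)/|U|) * sum_i log(|n(x_i) ∩ [x_i]_D|^2 / (|U| |[x_i]_D|))``,

  equivalently ``-(p/|U|) * sum_i log(credibility_i * coverage_i)`` where
  credibility ``|n ∩ [x]_D| / |[x]_D|`` measures how much of the
  sample's decision class its granule captures and coverage
  ``|n ∩ [x]_D| / |U|`` how much of the universe.  This is the measure
  the greedy reduction maximizes.

Logarithms default to base 10; the decision neighborhood entropy is
monotone non-decreasing under attribute addition and dominates the
precision-weighted average on every subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .system import (
    DecisionPartition,
    NeighborhoodDecisionSystem,
    NeighborhoodIndex,
    decision_approximations,
    decision_partition,
    neighborhoods,
)

__all__ = [
    "EntropyConfig",
    "RuleDegrees",
    "point_neighborhood_entropy",
    "average_neighborhood_entropy_hu",
    "average_neighborhood_entropy",
    "decision_neighborhood_entropy",
    "rule_degrees",
    "sig_in",
    "sig_out",
    "MEASURES",
]


@dataclass(frozen=True)
class EntropyConfig:
    """Numeric conventions shared by all entropy computations.

    log_base : base of the logarithm (> 1); base 10 reproduces the
        published worked-example values.
    tolerance : absolute tolerance for entropy-equality comparisons
        (greedy termination, reduct checks).
    """

    log_base: float = 10.0
    tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if self.log_base <= 1.0:
            raise ValueError("log_base must exceed 1")
        if self.tolerance < 0.0:
            raise ValueError("tolerance must be nonnegative")

    def log(self, x):
        return np.log(x) / math.log(self.log_base)


DEFAULT_CONFIG = EntropyConfig()


@dataclass(frozen=True)
class RuleDegrees:
    """Credibility and coverage of one sample's decision rule."""

    credibility: float
    coverage: float


def point_neighborhood_entropy(
    index: NeighborhoodIndex, i: int, config: EntropyConfig = DEFAULT_CONFIG
) -> float:
    """Entropy -log(|n(x_i)| / |U|) of a single sample's granule."""
    n = index.n_samples
    size = int(index.adjacency[i].sum())
    return float(-config.log(size / n))


def average_neighborhood_entropy_hu(
    index: NeighborhoodIndex, config: EntropyConfig = DEFAULT_CONFIG
) -> float:
    """Plain mean of the point entropies over the universe."""
    n = index.n_samples
    sizes = index.sizes
    return float(-config.log(sizes / n).sum() / n)


def average_neighborhood_entropy(
    system: NeighborhoodDecisionSystem,
    subset: Iterable[int | str] | None,
    config: EntropyConfig = DEFAULT_CONFIG,
) -> float:
    """Precision-weighted average neighborhood entropy of a subset.

    The plain average multiplied by the approximate precision p_B(D);
    bounded by [0, log |U|].
    """
    index = neighborhoods(system, subset)
    part = decision_partition(system)
    summary = decision_approximations(index, part)
    return float(summary.precision * average_neighborhood_entropy_hu(index, config))


def _intersection_sizes(index: NeighborhoodIndex, partition: DecisionPartition) -> np.ndarray:
    """|n(x_i) ∩ [x_i]_D| for every sample (always >= 1)."""
    mask = partition.class_mask()[partition.class_of]  # (n, n) same-class indicator
    sizes = (index.adjacency & mask).sum(axis=1)
    if (sizes < 1).any():
        # x is in both n(x) and [x]_D, so a zero means a broken index
        raise RuntimeError("empty neighborhood/decision-class intersection")
    return sizes


def decision_neighborhood_entropy(
    system: NeighborhoodDecisionSystem,
    subset: Iterable[int | str] | None,
    config: EntropyConfig = DEFAULT_CONFIG,
) -> float:
    """Decision neighborhood entropy H(D, B) of an attribute subset.

    ``-(p_B(D)/|U|) * sum_i log(|n(x_i) ∩ [x_i]_D|^2 / (|U| |[x_i]_D|))``.
    Nonnegative, monotone under attribute addition, and at least the
    precision-weighted average entropy of the same subset.
    """
    index = neighborhoods(system, subset)
    part = decision_partition(system)
    summary = decision_approximations(index, part)
    if summary.precision == 0.0:
        return 0.0
    n = system.n_samples
    inter = _intersection_sizes(index, part)
    class_sizes = part.class_sizes[part.class_of]
    terms = config.log(inter.astype(float) ** 2 / (n * class_sizes))
    return float(-summary.precision / n * terms.sum())


def rule_degrees(
    index: NeighborhoodIndex, partition: DecisionPartition, i: int
) -> RuleDegrees:
    """Credibility and coverage of sample ``i``'s decision rule."""
    members = partition.classes[partition.class_of[i]]
    inter = int(index.adjacency[i, members].sum())
    return RuleDegrees(
        credibility=inter / len(members),
        coverage=inter / index.n_samples,
    )


def sig_in(
    system: NeighborhoodDecisionSystem,
    a: int | str,
    subset: Iterable[int | str],
    config: EntropyConfig = DEFAULT_CONFIG,
) -> float:
    """Inner significance of attribute ``a`` inside ``subset``:
    H(D, B) - H(D, B - {a}).  Nonnegative by monotonicity."""
    cols = system.resolve_subset(subset)
    (a_idx,) = system.resolve_subset([a])
    if a_idx not in cols:
        raise ValueError("sig_in requires the attribute to belong to the subset")
    rest = tuple(k for k in cols if k != a_idx)
    return decision_neighborhood_entropy(system, cols, config) - decision_neighborhood_entropy(
        system, rest, config
    )


def sig_out(
    system: NeighborhoodDecisionSystem,
    a: int | str,
    subset: Iterable[int | str],
    config: EntropyConfig = DEFAULT_CONFIG,
) -> float:
    """Outer significance of attribute ``a`` for ``subset``:
    H(D, B ∪ {a}) - H(D, B); for B = ∅ this is H(D, {a})."""
    cols = system.resolve_subset(subset)
    (a_idx,) = system.resolve_subset([a])
    if a_idx in cols:
        raise ValueError("sig_out requires the attribute to lie outside the subset")
    return decision_neighborhood_entropy(
        system, cols + (a_idx,), config
    ) - decision_neighborhood_entropy(system, cols, config)


def _measure_point(system, subset, config=DEFAULT_CONFIG):
    index = neighborhoods(system, subset)
    return np.array(
        [point_neighborhood_entropy(index, i, config) for i in range(index.n_samples)]
    )


def _measure_average(system, subset, config=DEFAULT_CONFIG):
    return average_neighborhood_entropy_hu(neighborhoods(system, subset), config)


# Uniform name -> callable registry so the CLI and tests can select a
# measure by name.  All take (system, subset, config).
MEASURES = {
    "point": _measure_point,
    "average": _measure_average,
    "precision-weighted": average_neighborhood_entropy,
    "decision": decision_neighborhood_entropy,
}
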