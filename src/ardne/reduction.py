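"""Greedy attribute reduction by decision neighborhood entropy (ARDNE).

Forward phase: starting from the empty subset, repeatedly add the
attribute whose addition maximizes the decision neighborhood entropy
(ties broken toward the smallest column index), until the entropy of the
selected subset matches the entropy of the full attribute set or an
iteration cap fires; plateau rounds still add, since only further
attributes can close the remaining entropy gap.

Backward phase: revisit the selected attributes in selection order and
drop any whose removal still leaves the subset at the full-set entropy.

The result preserves the full-set decision neighborhood entropy while
discarding redundant attributes; monotonicity of the entropy guarantees
the forward trace never decreases.  A brute-force enumerator of minimal
entropy-preserving subsets serves as an exact oracle on small tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import numpy as np

from .entropy import EntropyConfig, decision_neighborhood_entropy
from .system import NeighborhoodDecisionSystem

__all__ = [
    "ReductionConfig",
    "TraceStep",
    "ReductResult",
    "ardne_reduce",
    "is_reduct",
    "brute_force_reducts",
]

BRUTE_FORCE_MAX_ATTRIBUTES = 20


@dataclass(frozen=True)
class ReductionConfig:
    """Knobs of the greedy reduction.

    delta : overrides the system's neighborhood radius when given.
    tolerance : absolute tolerance for entropy-equality tests.
    max_iterations : cap on forward selections (default: all attributes).
    log_base : logarithm base for the entropy.
    """

    delta: float | None = None
    tolerance: float = 1e-12
    max_iterations: int | None = None
    log_base: float = 10.0

    def entropy_config(self) -> EntropyConfig:
        return EntropyConfig(log_base=self.log_base, tolerance=self.tolerance)


@dataclass(frozen=True)
class TraceStep:
    iteration: int
    attribute: int
    attribute_name: str
    entropy: float


@dataclass(frozen=True)
class ReductResult:
    """Outcome of one greedy reduction run."""

    reduct: tuple[int, ...]
    attribute_names: tuple[str, ...]
    trace: tuple[TraceStep, ...]
    pruned: tuple[int, ...]
    full_entropy: float
    entropy: float
    terminated_by: str  # entropy-reached | no-improvement | iteration-cap
    selection_order: tuple[int, ...] = field(default=())


def _prepare(
    system: NeighborhoodDecisionSystem, config: ReductionConfig | None
) -> tuple[NeighborhoodDecisionSystem, ReductionConfig, EntropyConfig]:
    config = config or ReductionConfig()
    if config.delta is not None:
        system = system.with_delta(config.delta)
    return system, config, config.entropy_config()


def ardne_reduce(
    system: NeighborhoodDecisionSystem, config: ReductionConfig | None = None
) -> ReductResult:
    """Run the greedy forward/backward reduction on a decision system."""
    system, config, ecfg = _prepare(system, config)
    m = system.n_attributes
    if m == 0:
        raise ValueError("cannot reduce a system with no attributes")
    tol = config.tolerance
    cap = config.max_iterations if config.max_iterations is not None else m

    def H(cols: tuple[int, ...]) -> float:
        return decision_neighborhood_entropy(system, cols, ecfg)

    full_entropy = H(tuple(range(m)))

    selected: list[int] = []
    trace: list[TraceStep] = []
    current = 0.0  # H(D, ∅) with the empty-subset convention
    terminated_by = "iteration-cap"
    iteration = 0
    while full_entropy - current > tol:
        if iteration >= cap or len(selected) == m:
            terminated_by = "iteration-cap"
            break
        # Every round adds the candidate maximizing the entropy, ties
        # broken toward the smallest attribute index; a plateau round
        # (no candidate strictly improves) still adds, since the
        # entropy gap to the full set can only be closed by further
        # attributes.  Termination is guaranteed: at worst R grows to C,
        # where the gap is zero by identity.
        best_attr = None
        best_entropy = -np.inf
        for a in range(m):
            if a in selected:
                continue
            h = H(tuple(sorted(selected + [a])))
            if h > best_entropy + tol:
                best_entropy = h
                best_attr = a
        if best_attr is None:  # no candidates left while a gap persists
            terminated_by = "no-improvement"
            break
        selected.append(best_attr)
        current = best_entropy
        iteration += 1
        trace.append(
            TraceStep(
                iteration=iteration,
                attribute=best_attr,
                attribute_name=system.attributes[best_attr],
                entropy=current,
            )
        )
    else:
        terminated_by = "entropy-reached"

    selection_order = tuple(selected)

    # Backward pruning: drop attributes whose removal keeps the subset
    # at the full-set entropy; process in selection order, mutating the
    # working subset as attributes fall out.
    pruned: list[int] = []
    working = list(selected)
    for a in selection_order:
        if len(working) <= 1:
            break
        candidate = tuple(sorted(k for k in working if k != a))
        if H(candidate) >= full_entropy - tol:
            working.remove(a)
            pruned.append(a)

    reduct = tuple(sorted(working))
    return ReductResult(
        reduct=reduct,
        attribute_names=tuple(system.attributes[k] for k in reduct),
        trace=tuple(trace),
        pruned=tuple(pruned),
        full_entropy=full_entropy,
        entropy=H(reduct),
        terminated_by=terminated_by,
        selection_order=selection_order,
    )


def is_reduct(
    system: NeighborhoodDecisionSystem,
    subset: Iterable[int | str],
    config: ReductionConfig | None = None,
) -> bool:
    """Check the two reduct conditions: the subset preserves the
    full-set decision neighborhood entropy, and every member is
    indispensable (removing it strictly lowers the entropy)."""
    system, config, ecfg = _prepare(system, config)
    cols = system.resolve_subset(subset)
    tol = config.tolerance
    h_full = decision_neighborhood_entropy(system, None, ecfg)
    h_subset = decision_neighborhood_entropy(system, cols, ecfg)
    if abs(h_subset - h_full) > tol:
        return False
    for a in cols:
        rest = tuple(k for k in cols if k != a)
        if decision_neighborhood_entropy(system, rest, ecfg) >= h_subset - tol:
            return False
    return True


def brute_force_reducts(
    system: NeighborhoodDecisionSystem, config: ReductionConfig | None = None
) -> list[tuple[int, ...]]:
    """Enumerate all minimal entropy-preserving attribute subsets.

    Exact but exponential; guarded to small attribute counts.  Returns
    the inclusion-minimal subsets whose decision neighborhood entropy
    equals the full set's, sorted by size then lexicographically.
    """
    system, config, ecfg = _prepare(system, config)
    m = system.n_attributes
    if m > BRUTE_FORCE_MAX_ATTRIBUTES:
        raise ValueError(
            f"brute-force enumeration is limited to {BRUTE_FORCE_MAX_ATTRIBUTES} "
            "attributes; use ardne_reduce for larger systems"
        )
    tol = config.tolerance
    h_full = decision_neighborhood_entropy(system, None, ecfg)
    preserving: list[tuple[int, ...]] = []
    for size in range(1, m + 1):
        for cols in combinations(range(m), size):
            if abs(decision_neighborhood_entropy(system, cols, ecfg) - h_full) <= tol:
                preserving.append(cols)
    minimal = [
        cols
        for cols in preserving
        if not any(set(other) < set(cols) for other in preserving)
    ]
    return sorted(minimal, key=lambda cols: (len(cols), cols))
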