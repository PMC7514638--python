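"""Built-in fixture table and a synthetic decision-system generator.

The generator emulates the shape of expression-matrix feature-selection
problems: a handful of class-informative continuous attributes (well
separated class means, Gaussian within-class spread) buried among
uninformative attributes that are pure uniform noise.  It makes every
stage of the pipeline testable without downloading real datasets; it
does not attempt realistic gene-gene covariance or batch structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import NeighborhoodDecisionSystem

__all__ = ["table1_fixture", "SyntheticSpec", "generate_synthetic"]


def table1_fixture() -> NeighborhoodDecisionSystem:
    """The standard 4-sample, 3-attribute demonstration table.

    Four samples x1..x4 with attributes a, b, c already in [0, 1], a
    binary decision (Y, Y, N, N) and radius 0.3.  Small enough that
    every neighborhood, approximation and entropy can be checked by
    hand; used throughout the test suite.
    """
    values = np.array(
        [
            [0.12, 0.41, 0.61],
            [0.21, 0.15, 0.14],
            [0.31, 0.11, 0.26],
            [0.61, 0.13, 0.23],
        ]
    )
    return NeighborhoodDecisionSystem(
        values=values,
        decisions=np.array(["Y", "Y", "N", "N"]),
        delta=0.3,
        attributes=("a", "b", "c"),
        samples=("x1", "x2", "x3", "x4"),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic decision system.

    n_samples : total rows; class labels balanced to within one sample.
    n_informative : attributes whose per-class means differ.
    n_noise : attributes drawn uniform on [0, 1] independent of class.
    n_classes : number of decision labels (>= 2).
    class_separation : spacing between adjacent class means on every
        informative attribute, in [0, 1] units before rescaling.
    noise_sd : within-class Gaussian spread of informative attributes.
    seed : generator seed; runs are fully deterministic given it.
    """

    n_samples: int = 40
    n_informative: int = 2
    n_noise: int = 8
    n_classes: int = 2
    class_separation: float = 0.6
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("need at least one informative attribute")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")
        if self.n_noise < 0:
            raise ValueError("n_noise must be nonnegative")


def generate_synthetic(
    spec: SyntheticSpec, delta: float = 0.15
) -> NeighborhoodDecisionSystem:
    """Draw a decision system from a :class:`SyntheticSpec`.

    Informative attributes get class means on an equally spaced grid
    (adjacent means ``class_separation`` apart, centered in [0, 1]) plus
    Gaussian noise; noise attributes are uniform on [0, 1].  Every
    column is then min-max rescaled to [0, 1], which preserves the
    scale contract without clipping spikes at the bounds.  Informative
    columns come first; the returned attribute names mark them
    ``inf0, inf1, ...`` versus ``noise0, noise1, ...``.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_classes

    # balanced labels to within +/- 1 sample, in round-robin order
    class_of = np.arange(n) % k

    centers = 0.5 + (np.arange(k) - (k - 1) / 2) * spec.class_separation
    cols = []
    names = []
    for j in range(spec.n_informative):
        col = centers[class_of] + rng.normal(0.0, spec.noise_sd, size=n)
        cols.append(col)
        names.append(f"inf{j}")
    for j in range(spec.n_noise):
        cols.append(rng.uniform(0.0, 1.0, size=n))
        names.append(f"noise{j}")
    values = np.column_stack(cols)

    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    span = np.where(span == 0.0, 1.0, span)
    values = (values - lo) / span

    labels = np.array([f"c{c}" for c in class_of])
    return NeighborhoodDecisionSystem(
        values=values,
        decisions=labels,
        delta=delta,
        attributes=tuple(names),
        samples=tuple(f"s{i}" for i in range(n)),
    )
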