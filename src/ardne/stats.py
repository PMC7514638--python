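"""Benchmark harness: cross-validated accuracy, rank tables, and the
Friedman / Bonferroni-Dunn comparison statistics.

Multiple feature-selection algorithms evaluated on multiple datasets are
compared nonparametrically: per dataset the algorithms are ranked by
accuracy (rank 1 best, ties sharing mean ranks), the Friedman statistic

    chi2_F = 12 N / (k (k+1)) * (sum_i R_i^2 - k (k+1)^2 / 4)

tests whether the k average ranks R_i over N datasets differ, its
Iman-Davenport transform F_F = (N-1) chi2_F / (N (k-1) - chi2_F) is
compared against an F distribution, and the Bonferroni-Dunn critical
distance CD = q_alpha * sqrt(k (k+1) / (6 N)) says how far two average
ranks must be apart to call the algorithms different at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC

from .system import NeighborhoodDecisionSystem

__all__ = [
    "RankTable",
    "ComparisonStats",
    "CLASSIFIERS",
    "Q_ALPHA",
    "cross_validate",
    "rank_algorithms",
    "friedman_test",
    "bonferroni_dunn_cd",
]


def _make_knn3():
    return KNeighborsClassifier(n_neighbors=3)


def _make_svm_linear():
    return SVC(kernel="linear")


CLASSIFIERS = {"knn3": _make_knn3, "svm-linear": _make_svm_linear}

# Two-tailed Bonferroni-Dunn critical values q_alpha for k compared
# algorithms (standard tabulation used with the critical-distance test).
Q_ALPHA = {
    0.05: {2: 1.960, 3: 2.241, 4: 2.394, 5: 2.498, 6: 2.576,
           7: 2.638, 8: 2.690, 9: 2.724, 10: 2.773},
    0.10: {2: 1.645, 3: 1.960, 4: 2.128, 5: 2.241, 6: 2.326,
           7: 2.394, 8: 2.450, 9: 2.498, 10: 2.539},
}


@dataclass(frozen=True)
class RankTable:
    """Per-dataset ranks of algorithms plus their column averages."""

    ranks: pd.DataFrame  # datasets x algorithms, rank 1 = best
    average_ranks: pd.Series

    @property
    def n_datasets(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_algorithms(self) -> int:
        return self.ranks.shape[1]


@dataclass(frozen=True)
class ComparisonStats:
    """Friedman chi-square, its F transform, and the critical distance."""

    chi_square: float
    f_statistic: float | None  # None when the denominator vanishes
    critical_distance: float | None = None
    q_alpha: float | None = None
    alpha: float | None = None


def cross_validate(
    system: NeighborhoodDecisionSystem,
    subset: Iterable[int | str] | None,
    classifier: str = "knn3",
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> float:
    """Mean repeated stratified k-fold accuracy on an attribute subset.

    The classifier is off-the-shelf (3-nearest-neighbors or a
    linear-kernel SVM); folds are stratified by class and the fold PRNG
    is seeded, so the returned accuracy is deterministic given the seed.
    """
    cols = system.resolve_subset(subset)
    if len(cols) == 0:
        raise ValueError("cross_validate requires a nonempty attribute subset")
    if classifier not in CLASSIFIERS:
        raise KeyError(f"unknown classifier {classifier!r}; options: {sorted(CLASSIFIERS)}")
    X = system.values[:, cols]
    y = LabelEncoder().fit_transform(system.decisions)
    counts = np.bincount(y)
    n_splits = int(folds)
    if counts.min() < n_splits:
        # stratification impossible at the requested fold count: shrink
        # to the largest feasible count, reject if even 2 is infeasible
        n_splits = int(counts.min())
        if n_splits < 2:
            raise ValueError(
                "a decision class has a single sample; stratified CV is impossible"
            )
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=repeats, random_state=seed)
    model = CLASSIFIERS[classifier]()
    scores = cross_val_score(model, X, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def rank_algorithms(accuracies: pd.DataFrame | np.ndarray) -> RankTable:
    """Rank algorithms per dataset, highest accuracy = rank 1.

    Tied accuracies share the mean of the tied rank positions, so every
    row of the result sums to k (k + 1) / 2.
    """
    frame = pd.DataFrame(accuracies)
    if frame.isna().any().any():
        raise ValueError("accuracy table has missing entries")
    ranked = frame.apply(lambda row: rankdata(-row.to_numpy(), method="average"), axis=1,
                         result_type="expand")
    ranked.columns = frame.columns
    return RankTable(ranks=ranked, average_ranks=ranked.mean(axis=0))


def friedman_test(ranks: RankTable) -> ComparisonStats:
    """Friedman chi-square and Iman-Davenport F from a rank table."""
    k = ranks.n_algorithms
    n = ranks.n_datasets
    if k < 2 or n < 2:
        raise ValueError("the Friedman test needs >= 2 algorithms and >= 2 datasets")
    r = ranks.average_ranks.to_numpy(dtype=float)
    chi_square = 12.0 * n / (k * (k + 1)) * (np.sum(r**2) - k * (k + 1) ** 2 / 4.0)
    denom = n * (k - 1) - chi_square
    f_statistic = (n - 1) * chi_square / denom if abs(denom) > 1e-12 else None
    return ComparisonStats(chi_square=float(chi_square), f_statistic=f_statistic)


def bonferroni_dunn_cd(
    k: int, n_datasets: int, q_alpha: float | None = None, alpha: float = 0.10
) -> float:
    """Bonferroni-Dunn critical distance q_alpha * sqrt(k (k+1) / (6 N)).

    When ``q_alpha`` is not given it is looked up in the built-in table
    for the requested ``alpha`` (0.05 or 0.10, k <= 10).
    """
    if k < 2 or n_datasets < 1:
        raise ValueError("need k >= 2 algorithms and N >= 1 datasets")
    if q_alpha is None:
        try:
            q_alpha = Q_ALPHA[round(alpha, 2)][k]
        except KeyError:
            raise KeyError(
                f"no tabulated q for alpha={alpha}, k={k}; pass q_alpha explicitly"
            ) from None
    if q_alpha <= 0:
        raise ValueError("q_alpha must be positive")
    return float(q_alpha * np.sqrt(k * (k + 1) / (6.0 * n_datasets)))
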