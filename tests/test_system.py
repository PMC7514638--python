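"""Granulation primitives: loading, distances, neighborhoods, approximations."""

import numpy as np
import pandas as pd
import pytest

from ardne.system import (
    NeighborhoodDecisionSystem,
    decision_approximations,
    decision_partition,
    distance,
    load_decision_system,
    lower_approximation,
    neighborhoods,
    normalize_min_max,
    pairwise_distances,
    upper_approximation,
)

from conftest import random_system


class TestValidation:
    def test_delta_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            NeighborhoodDecisionSystem(
                values=[[0.1]], decisions=["Y"], delta=1.5
            )

    def test_missing_value_rejected(self):
        with pytest.raises(ValueError, match="row 0, column 1"):
            NeighborhoodDecisionSystem(
                values=[[0.1, np.nan]], decisions=["Y"], delta=0.3
            )

    def test_minimal_single_sample_system(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text("a,d\n0.5,Y\n")
        sys_ = load_decision_system(path, delta=0.3)
        assert sys_.n_samples == 1 and sys_.n_attributes == 1

    def test_duplicate_subset_rejected(self, table1):
        with pytest.raises(ValueError, match="duplicate"):
            table1.resolve_subset(["a", "a"])


class TestLoading:
    def test_table1_roundtrip(self, table1, tmp_path):
        path = tmp_path / "t1.csv"
        frame = pd.DataFrame(table1.values, columns=list(table1.attributes))
        frame["d"] = table1.decisions
        frame.to_csv(path, index=False)
        sys_ = load_decision_system(path, delta=0.3)
        assert sys_.n_samples == 4 and sys_.n_attributes == 3
        assert list(sys_.decisions) == ["Y", "Y", "N", "N"]
        np.testing.assert_allclose(sys_.values, table1.values)

    def test_non_numeric_cell_names_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,d\n0.1,NA,Y\n0.2,0.3,N\n")
        with pytest.raises(ValueError, match="'b'"):
            load_decision_system(path, delta=0.3)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("a,d\n")
        with pytest.raises(ValueError, match="no data rows"):
            load_decision_system(path, delta=0.3)


class TestNormalize:
    def test_column_rescaled(self):
        sys_ = NeighborhoodDecisionSystem(
            values=[[0.0], [5.0], [10.0]], decisions=list("YYN"), delta=0.3
        )
        out = normalize_min_max(sys_)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        sys_ = NeighborhoodDecisionSystem(
            values=[[2.0], [2.0], [2.0]], decisions=list("YYN"), delta=0.3
        )
        assert (normalize_min_max(sys_).values == 0.0).all()

    def test_normalization_is_opt_in_and_changes_table1(self, table1):
        # column a spans [0.12, 0.61]; rescaling stretches it
        out = normalize_min_max(table1)
        np.testing.assert_allclose(
            out.values[:, 0], [0.0, 0.09 / 0.49, 0.19 / 0.49, 1.0], atol=1e-12
        )


class TestDistance:
    # the six pairwise distances on attribute a of the worked example
    @pytest.mark.parametrize(
        "i,j,expected",
        [(0, 1, 0.09), (0, 2, 0.19), (0, 3, 0.49), (1, 2, 0.10), (1, 3, 0.40), (2, 3, 0.30)],
    )
    def test_single_attribute_pairs(self, table1, i, j, expected):
        assert distance(table1, ["a"], i, j) == pytest.approx(expected, abs=1e-12)

    def test_self_distance_zero(self, table1):
        assert distance(table1, ["a", "b", "c"], 2, 2) == 0.0

    def test_two_attribute_pythagoras(self, table1):
        assert distance(table1, ["a", "b"], 0, 1) == pytest.approx(
            np.hypot(0.09, 0.26), abs=1e-12
        )

    def test_empty_subset_rejected(self, table1):
        with pytest.raises(ValueError, match="nonempty"):
            distance(table1, [], 0, 1)


class TestNeighborhoods:
    def test_worked_example_neighbor_sets(self, table1):
        idx = neighborhoods(table1, ["a"])
        expected = [[0, 1, 2], [0, 1, 2], [0, 1, 2, 3], [2, 3]]
        for i, want in enumerate(expected):
            assert list(idx.neighbors(i)) == want

    def test_boundary_distance_is_inclusive(self, table1):
        # d(x3, x4) on {a} equals delta = 0.3 exactly; both are neighbors
        idx = neighborhoods(table1, ["a"])
        assert idx.adjacency[2, 3] and idx.adjacency[3, 2]

    def test_huge_delta_gives_universe(self):
        sys_ = random_system(3).with_delta(1.0)
        m = sys_.n_attributes
        # delta >= sqrt(m) on [0,1] data cannot exclude anybody; emulate
        # by scaling values into [0, 1/sqrt(m)]
        shrunk = NeighborhoodDecisionSystem(
            values=sys_.values / np.sqrt(m), decisions=sys_.decisions, delta=1.0
        )
        assert neighborhoods(shrunk, None).adjacency.all()

    def test_empty_subset_neighborhood_is_universe(self, table1):
        assert neighborhoods(table1, []).adjacency.all()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_double_loop_oracle(self, seed):
        sys_ = random_system(seed)
        idx = neighborhoods(sys_, None)
        for i in range(sys_.n_samples):
            for j in range(sys_.n_samples):
                d = distance(sys_, None, i, j)
                assert idx.adjacency[i, j] == (d <= sys_.delta + 1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_reflexive_symmetric_and_monotone_in_delta(self, seed):
        sys_ = random_system(seed)
        idx = neighborhoods(sys_, None)
        assert np.diag(idx.adjacency).all()
        assert (idx.adjacency == idx.adjacency.T).all()
        wider = neighborhoods(sys_, None, delta=min(1.0, sys_.delta + 0.2))
        assert (wider.adjacency | ~idx.adjacency).all()  # superset

    @pytest.mark.parametrize("seed", range(12))
    def test_anti_monotone_in_attribute_subset(self, seed):
        sys_ = random_system(seed)
        full = neighborhoods(sys_, None)
        for k in range(sys_.n_attributes):
            sub = neighborhoods(sys_, [k])
            # adding attributes never grows a neighborhood
            assert (sub.adjacency | ~full.adjacency).all()


class TestPartitionAndApproximations:
    def test_table1_partition(self, table1):
        part = decision_partition(table1)
        assert part.labels == ("Y", "N")
        assert [list(c) for c in part.classes] == [[0, 1], [2, 3]]

    def test_all_labels_identical_single_class(self):
        sys_ = NeighborhoodDecisionSystem(
            values=np.eye(3), decisions=list("AAA"), delta=0.3
        )
        part = decision_partition(sys_)
        assert len(part.classes) == 1 and len(part.classes[0]) == 3

    def test_all_labels_distinct_singletons(self):
        sys_ = NeighborhoodDecisionSystem(
            values=np.eye(3), decisions=list("ABC"), delta=0.3
        )
        assert all(len(c) == 1 for c in decision_partition(sys_).classes)

    def test_lower_approximation_worked_example(self, table1):
        idx = neighborhoods(table1, ["a"])
        assert list(lower_approximation(idx, [2, 3])) == [3]
        assert list(lower_approximation(idx, [0, 1])) == []
        assert list(lower_approximation(idx, range(4))) == [0, 1, 2, 3]

    def test_upper_approximation_worked_example(self, table1):
        idx = neighborhoods(table1, ["a"])
        assert list(upper_approximation(idx, [0, 1])) == [0, 1, 2]
        assert list(upper_approximation(idx, [])) == []
        assert list(upper_approximation(idx, range(4))) == [0, 1, 2, 3]

    @pytest.mark.parametrize("subset,lower,precision", [(["a"], [3], 0.25), (["c"], [0], 0.25)])
    def test_decision_approximations_table1(self, table1, subset, lower, precision):
        summary = decision_approximations(
            neighborhoods(table1, subset), decision_partition(table1)
        )
        assert list(summary.lower) == lower
        assert list(summary.upper) == [0, 1, 2, 3]
        assert summary.precision == pytest.approx(precision)

    def test_zero_delta_distinct_rows_full_precision(self):
        sys_ = NeighborhoodDecisionSystem(
            values=[[0.0], [0.5], [1.0]], decisions=list("YNY"), delta=0.0
        )
        summary = decision_approximations(
            neighborhoods(sys_, None), decision_partition(sys_)
        )
        assert list(summary.lower) == [0, 1, 2]
        assert summary.precision == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_upper_of_decision_is_universe_and_lower_subset(self, seed):
        sys_ = random_system(seed)
        idx = neighborhoods(sys_, None)
        part = decision_partition(sys_)
        summary = decision_approximations(idx, part)
        assert list(summary.upper) == list(range(sys_.n_samples))
        assert set(summary.lower) <= set(summary.upper)
        assert 0.0 <= summary.precision <= 1.0


def test_pairwise_distance_matrix_consistent(table1):
    mat = pairwise_distances(table1, ["a", "c"])
    assert mat.shape == (4, 4)
    assert mat[0, 1] == pytest.approx(distance(table1, ["a", "c"], 0, 1))
    assert (mat == mat.T).all() and (np.diag(mat) == 0).all()
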