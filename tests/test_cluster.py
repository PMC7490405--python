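import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhertype.cluster import (ClusterTypology, WSSCurve, bootstrap_stability,
                               jaccard, kmeans_fit, order_clusters,
                               select_k_elbow, select_scaling, wss_curve)


def blobs(centers, n_per=30, spread=0.5, seed=0):
    rng = np.random.default_rng(seed)
    return np.vstack([c + rng.normal(0, spread, size=(n_per, len(c)))
                      for c in np.atleast_2d(centers)])


class TestKMeans:
    def test_k1_wss_is_total_sum_of_squares(self):
        X = blobs([[0.0, 0.0]], n_per=50, spread=2.0)
        sol = kmeans_fit(X, 1, seed=0)
        tss = ((X - X.mean(axis=0)) ** 2).sum()
        assert sol.wss_total == pytest.approx(tss)

    def test_two_separated_groups_recovered_exactly(self):
        X = blobs([[0, 0], [100, 100]], spread=0.1, seed=1)
        sol = kmeans_fit(X, 2, seed=0)
        labels = sol.labels.to_numpy()
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equal_to_n_gives_zero_wss(self):
        X = np.arange(6, dtype=float)[:, None]
        assert kmeans_fit(X, 6, seed=0).wss_total == pytest.approx(0.0)

    def test_k_beyond_distinct_points_rejected(self):
        X = np.array([[0.0], [0.0], [1.0]])
        with pytest.raises(ValueError):
            kmeans_fit(X, 3, seed=0)


class TestWSSCurve:
    def test_deterministic_given_seed(self):
        X = blobs([[0, 0], [5, 5], [10, 0]], seed=2)
        a = wss_curve(X, range(1, 8), seed=9)
        b = wss_curve(X, range(1, 8), seed=9)
        assert np.array_equal(a.wss, b.wss)

    def test_monotone_non_increasing(self):
        X = blobs([[0, 0], [5, 5], [10, 0]], seed=3)
        curve = wss_curve(X, range(1, 11), seed=4)
        assert (np.diff(curve.wss) <= 1e-8).all()

    def test_identical_points_give_zero_everywhere(self):
        X = np.ones((10, 2))
        curve = wss_curve(X, range(1, 4), n_init=2, seed=0)
        assert np.allclose(curve.wss, 0.0)


class TestElbow:
    def test_normalized_chord_rule_on_reference_curve(self):
        curve = WSSCurve(np.arange(1, 6), np.array([100, 50, 2, 1.5, 1.0]))
        assert select_k_elbow(curve) == 3

    def test_flat_curve_returns_one_with_warning(self):
        curve = WSSCurve(np.arange(1, 6), np.full(5, 7.0))
        with pytest.warns(UserWarning, match="flat"):
            assert select_k_elbow(curve) == 1

    def test_linear_curve_ties_to_smallest_interior_k(self):
        curve = WSSCurve(np.arange(1, 6), np.array([50, 40, 30, 20, 10.0]))
        with pytest.warns(UserWarning, match="linear"):
            assert select_k_elbow(curve) == 2

    def test_manual_override_wins(self):
        curve = WSSCurve(np.arange(1, 6), np.array([100, 50, 2, 1.5, 1.0]))
        assert select_k_elbow(curve, override=5) == 5

    def test_three_separated_groups_produce_elbow_at_three(self):
        X = blobs([[0, 0], [30, 0], [0, 30]], spread=0.5, seed=5)
        curve = wss_curve(X, range(1, 10), seed=6)
        assert select_k_elbow(curve) == 3


class TestJaccard:
    @pytest.mark.parametrize("a,b,expected", [
        ({1, 2, 3}, {1, 2, 3}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        ({1, 2, 3}, {2, 3, 4}, 0.5),
        (set(), set(), 0.0),
        (set(), {1}, 0.0),
    ])
    def test_values(self, a, b, expected):
        assert jaccard(a, b) == expected

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0.0 <= j <= 1.0
        if a or b:
            assert (j == 1.0) == (a == b)


class TestBootstrapStability:
    def test_zero_bootstraps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_stability(np.zeros((10, 2)), 2, n_bootstrap=0, seed=0)

    def test_well_separated_groups_are_stable(self):
        X = blobs([[0, 0], [20, 0], [0, 20]], n_per=40, spread=1.0, seed=7)
        rep = bootstrap_stability(X, 3, n_bootstrap=200, seed=11)
        assert (rep.mean_jaccard >= 0.95).all()
        assert (rep.dissolution_rate <= 0.01).all()

    def test_structureless_data_shows_elevated_dissolution(self):
        rng = np.random.default_rng(13)
        U = rng.uniform(0, 1, size=(120, 5))
        rep = bootstrap_stability(U, 3, n_bootstrap=200, seed=12)
        assert rep.dissolution_rate.max() > 0.2


@pytest.fixture(scope="module")
def measure_matrix():
    import adhertype as at
    data = at.generate_cohort(at.CohortConfig(n_patients=90, seed=55))
    grids = at.build_dose_grid(data.events, data.malfunctions,
                               data.followup_windows)
    return at.cohort_measure_matrix(at.compute_profile(g)
                                    for g in grids.values())


class TestScalingSelection:
    def test_single_method_is_returned(self, measure_matrix):
        best, evals = select_scaling(measure_matrix, ["min_max"],
                                     n_bootstrap=10, seed=1)
        assert best.method == "min_max" and list(evals) == ["min_max"]

    def test_winner_has_highest_mean_jaccard(self, measure_matrix):
        best, evals = select_scaling(measure_matrix, n_bootstrap=30, seed=2)
        top = max(e.stability.overall_mean_jaccard for e in evals.values())
        assert best.stability.overall_mean_jaccard == top

    def test_default_cohort_yields_three_clusters_per_method(self, measure_matrix):
        _, evals = select_scaling(measure_matrix, n_bootstrap=10, seed=3)
        assert all(e.k == 3 for e in evals.values())


class TestClusterOrdering:
    def test_renumbered_by_ascending_median_adherence(self):
        labels = pd.Series([0] * 4 + [1] * 4 + [2] * 4,
                           index=[f"P{i}" for i in range(12)])
        a = pd.Series([91] * 4 + [16] * 4 + [55] * 4, index=labels.index,
                      dtype=float)
        from adhertype.cluster import ClusterSolution
        sol = ClusterSolution(3, labels, np.zeros((3, 1)), 0.0, 25)
        ordered = order_clusters(sol, a)
        assert ordered.labels[a == 16].unique().tolist() == [1]
        assert ordered.labels[a == 55].unique().tolist() == [2]
        assert ordered.labels[a == 91].unique().tolist() == [3]

    def test_k1_identity(self):
        from adhertype.cluster import ClusterSolution
        labels = pd.Series([0, 0, 0], index=["a", "b", "c"])
        sol = ClusterSolution(1, labels, np.zeros((1, 1)), 1.0, 25)
        ordered = order_clusters(sol, pd.Series([1.0, 2, 3], index=labels.index))
        assert (ordered.labels == 1).all()

    def test_median_tie_broken_by_size_descending(self):
        labels = pd.Series([0, 0, 1, 1, 1], index=list("abcde"))
        a = pd.Series([50.0, 50, 50, 50, 50], index=labels.index)
        from adhertype.cluster import ClusterSolution
        sol = ClusterSolution(2, labels, np.zeros((2, 1)), 0.0, 25)
        ordered = order_clusters(sol, a)
        # larger cluster first
        assert ordered.labels["c"] == 1 and ordered.labels["a"] == 2


def test_cluster_typology_estimator_roundtrip():
    X = blobs([[0, 0], [25, 0], [0, 25]], n_per=25, spread=0.8, seed=21)
    est = ClusterTypology(random_state=3).fit(X)
    assert est.k_ == 3
    assert len(est.labels_) == len(X)
    rep = est.bootstrap_stability(X, n_bootstrap=25)
    assert (rep.mean_jaccard > 0.9).all()
    assert est.get_params()["n_init"] == 25
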