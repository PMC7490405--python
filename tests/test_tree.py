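import numpy as np
import pandas as pd
import pytest

from adhertype.measures import MEASURE_NAMES
from adhertype.tree import (CARTParams, ConfusionMatrix,
                            SurrogateTreeClassifier, accuracy, evaluate,
                            fit_cart, select_best_measure, split_data)


class TestSplit:
    def test_protocol_sizes_at_n211(self):
        split = split_data([f"P{i}" for i in range(211)], seed=0)
        assert len(split.test) == 32
        assert len(split.validation) == 32
        assert len(split.train) == 147

    def test_degenerate_all_training(self):
        split = split_data(list("abcdef"), fractions=(1.0, 0.0, 0.0), seed=0)
        assert len(split.train) == 6 and not split.validation and not split.test

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            split_data(list("abc"), fractions=(0.5, 0.2, 0.2), seed=0)

    def test_partitions_disjoint_exhaustive_and_seeded(self):
        ids = [f"P{i}" for i in range(50)]
        a = split_data(ids, seed=7)
        b = split_data(ids, seed=7)
        assert a == b
        union = set(a.train) | set(a.validation) | set(a.test)
        assert union == set(ids)


def gini_oracle(x, y):
    """Exhaustive search over midpoints for the single best Gini split."""
    order = np.argsort(x)
    xs, ys = np.asarray(x)[order], np.asarray(y)[order]
    classes = np.unique(ys)
    n = len(ys)

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        _, c = np.unique(labels, return_counts=True)
        p = c / len(labels)
        return 1.0 - (p ** 2).sum()

    best = (np.inf, None)
    for i in range(n - 1):
        if xs[i] == xs[i + 1]:
            continue
        w = (i + 1) / n * gini(ys[:i + 1]) + (n - i - 1) / n * gini(ys[i + 1:])
        if w < best[0] - 1e-12:
            best = (w, (xs[i] + xs[i + 1]) / 2)
    return best


class TestCART:
    def test_separable_labels_give_single_split_perfect_fit(self):
        x = np.concatenate([np.linspace(0, 10, 30), np.linspace(50, 60, 30)])
        y = np.array([1] * 30 + [2] * 30)
        tree = fit_cart(x, y, seed=0)
        assert (tree.predict(x) == y).all()
        assert tree.tree_.get_depth() == 1

    def test_constant_predictor_gives_root_only_majority(self):
        x = np.full(40, 3.14)
        y = np.array([1] * 25 + [2] * 15)
        tree = fit_cart(x, y, seed=0)
        assert tree.tree_.get_depth() == 0
        assert (tree.predict(x) == 1).all()

    def test_two_threshold_labels_recovered_by_depth_two_tree(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.uniform(0, 30, 20), rng.uniform(40, 70, 20),
                            rng.uniform(80, 100, 20)])
        y = np.where(x < 35, 1, np.where(x > 75, 3, 2))
        tree = fit_cart(x, y, seed=0)
        assert (tree.predict(x) == y).all()
        d = tree.to_dict()["root"]
        thresholds = sorted([d["threshold"], d["left"]["threshold"]
                             if not d["left"]["leaf"] else d["right"]["threshold"]])
        assert 30 <= thresholds[0] <= 40 and 70 <= thresholds[1] <= 80

    def test_fewer_than_min_split_patients_warns_and_fits_root(self, caplog):
        x = np.arange(10, dtype=float)
        y = np.array([1] * 6 + [2] * 4)
        with caplog.at_level("WARNING"):
            tree = fit_cart(x, y, CARTParams(min_split=20, min_leaf=6,
                                             max_depth=2), seed=0)
        assert "root-only" in caplog.text
        assert tree.tree_.get_depth() == 0

    def test_depth_one_tree_matches_exhaustive_gini_search(self):
        rng = np.random.default_rng(99)
        for trial in range(25):
            n = int(rng.integers(20, 200))
            x = rng.normal(size=n)
            cut = np.quantile(x, rng.uniform(0.25, 0.75))
            y = (x > cut).astype(int)
            flip = rng.random(n) < 0.05
            y[flip] = 1 - y[flip]
            if len(np.unique(y)) < 2:
                continue
            est = SurrogateTreeClassifier(min_split=2, min_leaf=1, max_depth=1,
                                          random_state=int(rng.integers(1e6)))
            est.fit(x, y)
            oracle_gini, _ = gini_oracle(x, y)
            t = est.tree_.tree_
            if t.children_left[0] == -1:  # pruned to the root: split useless
                continue
            left = x <= t.threshold[0]
            def gini(lab):
                _, c = np.unique(lab, return_counts=True)
                p = c / len(lab)
                return 1 - (p ** 2).sum()
            got = (left.mean() * gini(y[left])
                   + (1 - left.mean()) * gini(y[~left]))
            assert got == pytest.approx(oracle_gini, abs=1e-10)

    def test_json_and_text_exports(self):
        x = np.concatenate([np.zeros(15), np.ones(15)])
        y = np.array([1] * 15 + [2] * 15)
        tree = fit_cart(x, y, seed=0)
        d = tree.to_dict()
        assert not d["root"]["leaf"] and d["root"]["n"] == 30
        assert "if A <=" in tree.to_text(measure="A")


TABLE_2 = ConfusionMatrix(np.array([[4, 2, 0], [1, 18, 0], [0, 0, 5]]),
                          classes=[1, 2, 3])


class TestEvaluation:
    def test_perfect_predictions_give_diagonal_matrix(self):
        x = np.array([0.0, 0, 1, 1, 2])
        y = np.array([1, 1, 2, 2, 3])
        tree = fit_cart(x, y, CARTParams(min_split=2, min_leaf=1), seed=0)
        cm = evaluate(tree, x, y)
        assert cm.total == 5
        assert np.trace(cm.counts) == 5

    def test_printed_confusion_matrix_diagonal(self):
        assert np.trace(TABLE_2.counts) == 27
        assert accuracy(TABLE_2) == pytest.approx(27 / TABLE_2.total)

    def test_single_class_labels_occupy_one_column(self):
        x = np.arange(10, dtype=float)
        y = np.ones(10, dtype=int)
        tree = fit_cart(x, y, CARTParams(min_split=2, min_leaf=1), seed=0)
        cm = evaluate(tree, x, y)
        nonzero_cols = np.flatnonzero(cm.counts.sum(axis=0))
        assert len(nonzero_cols) == 1

    @pytest.mark.parametrize("counts,expected", [
        (np.eye(3, dtype=int) * 4, 1.0),
        (np.array([[0, 5], [5, 0]]), 0.0),
    ])
    def test_accuracy_extremes(self, counts, expected):
        assert accuracy(ConfusionMatrix(counts, list(range(len(counts))))) \
            == expected

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(np.zeros((2, 2), dtype=int), [1, 2]))

    def test_empty_partition_rejected(self):
        x = np.arange(10, dtype=float)
        y = (x > 4).astype(int)
        tree = fit_cart(x, y, CARTParams(min_split=2, min_leaf=1), seed=0)
        with pytest.raises(ValueError):
            evaluate(tree, np.array([]), np.array([]))


class TestMeasureSelection:
    def _matrix(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.uniform(0, 100, size=(n, 5)),
                         columns=list(MEASURE_NAMES),
                         index=[f"P{i:03d}" for i in range(n)])
        return m

    def test_perfectly_predictive_measure_wins(self):
        m = self._matrix()
        labels = pd.Series((m["C"] > 50).astype(int) + 1, index=m.index)
        split = split_data(list(m.index), seed=1)
        best, accs, trees = select_best_measure(m, labels, split, seed=2)
        assert best == "C"
        assert accs["C"] == 1.0

    def test_ties_break_toward_earlier_measure(self):
        m = self._matrix(seed=3)
        m["B"] = m["A"]  # identical predictors -> identical accuracy
        labels = pd.Series((m["A"] > 50).astype(int) + 1, index=m.index)
        split = split_data(list(m.index), seed=1)
        best, accs, _ = select_best_measure(m, labels, split, seed=2)
        assert accs["A"] == accs["B"]
        assert best == "A"
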