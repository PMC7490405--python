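"""Univariate CART surrogates for the cluster typology.

A shallow classification tree is fitted per adherence measure against the
cluster labels, so that clinicians can approximate the multi-measure
typology from a single number. Constraints follow the protocol: a node
needs >= 20 patients to split, every leaf holds >= 6, the tree is at most
two split levels deep, and the cost-complexity pruning level is chosen by
10-fold cross-validation. Data are split 70/15/15 into training, a
validation partition that picks the best measure, and a held-out test
partition that yields the final confusion matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from ._rng import derive_seed
from .measures import MEASURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "CARTParams",
    "DataSplit",
    "ConfusionMatrix",
    "SurrogateTreeClassifier",
    "split_data",
    "fit_cart",
    "select_best_measure",
    "evaluate",
    "accuracy",
]


@dataclass(frozen=True)
class CARTParams:
    min_split: int = 20
    min_leaf: int = 6
    max_depth: int = 2
    cv_folds: int = 10

    def __post_init__(self):
        if self.min_leaf < 1 or self.max_depth < 1 or self.min_split < 2:
            raise ValueError("invalid CART constraints")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


@dataclass(frozen=True)
class DataSplit:
    """Disjoint, exhaustive train/validation/test membership."""

    train: tuple
    validation: tuple
    test: tuple
    fractions: tuple[float, float, float]
    seed: int | None

    def __post_init__(self):
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = len(self.train) + len(self.validation) + len(self.test)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("partitions must be disjoint")


def split_data(patient_ids, fractions=(0.70, 0.15, 0.15),
               seed: int | None = None) -> DataSplit:
    """Uniform random, unstratified partition into train/validation/test.

    The validation and test sizes are the nearest-integer allocations of
    their fractions; the remainder goes to training (so n = 211 with
    0.70/0.15/0.15 gives 147/32/32).
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three numbers summing to 1")
    if min(fractions) < 0:
        raise ValueError("fractions must be non-negative")
    ids = list(patient_ids)
    n = len(ids)
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("rounded partition sizes exceed the cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [ids[i] for i in perm]
    return DataSplit(train=tuple(shuffled[:n_train]),
                     validation=tuple(shuffled[n_train:n_train + n_val]),
                     test=tuple(shuffled[n_train + n_val:]),
                     fractions=fractions, seed=seed)


class SurrogateTreeClassifier(BaseEstimator, ClassifierMixin):
    """Constrained, CV-pruned CART on a single continuous predictor.

    Greedy Gini splits honouring ``min_split``/``min_leaf``/``max_depth``;
    the cost-complexity parameter is the candidate from the nested pruning
    sequence that minimises 10-fold cross-validated misclassification
    (ties toward the simpler tree). Folds are label-stratified and seeded.
    """

    def __init__(self, min_split: int = 20, min_leaf: int = 6,
                 max_depth: int = 2, cv_folds: int = 10,
                 random_state: int | None = None):
        self.min_split = min_split
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.cv_folds = cv_folds
        self.random_state = random_state

    @staticmethod
    def _column(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[1] != 1:
            raise ValueError("the surrogate tree is univariate: one predictor")
        return arr

    def _make_tree(self, ccp_alpha: float = 0.0) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion="gini", min_samples_split=self.min_split,
            min_samples_leaf=self.min_leaf, max_depth=self.max_depth,
            ccp_alpha=ccp_alpha, random_state=self.random_state)

    def fit(self, X, y):
        x = self._column(X)
        y = np.asarray(y)
        n = len(y)
        if n < self.min_split:
            logger.warning("only %d patients (< min_split=%d): root-only tree",
                           n, self.min_split)
        full = self._make_tree().fit(x, y)
        self.ccp_alpha_ = self._select_alpha(x, y, full)
        self.tree_ = self._make_tree(self.ccp_alpha_).fit(x, y)
        self.classes_ = self.tree_.classes_
        return self

    def _select_alpha(self, x, y, full: DecisionTreeClassifier) -> float:
        path = full.cost_complexity_pruning_path(x, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        if len(alphas) <= 1:
            return float(alphas[0]) if len(alphas) else 0.0
        _, class_counts = np.unique(y, return_counts=True)
        n_splits = int(min(self.cv_folds, class_counts.min()))
        if n_splits < 2:
            return 0.0
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                             random_state=self.random_state)
        err = np.zeros(len(alphas))
        for tr, te in cv.split(x, y):
            for j, a in enumerate(alphas):
                pred = self._make_tree(a).fit(x[tr], y[tr]).predict(x[te])
                err[j] += (pred != y[te]).sum()
        best = err.min()
        # among CV-optimal alphas, prefer the largest (simplest tree)
        return float(alphas[np.flatnonzero(err <= best)[-1]])

    def predict(self, X):
        return self.tree_.predict(self._column(X))

    # -- export ----------------------------------------------------------
    def to_dict(self) -> dict:
        t = self.tree_.tree_

        def node(i: int) -> dict:
            if t.children_left[i] == -1:
                counts = t.value[i][0]
                return {"leaf": True,
                        "class": self.classes_[int(np.argmax(counts))].item()
                        if hasattr(self.classes_[0], "item")
                        else self.classes_[int(np.argmax(counts))],
                        "n": int(t.n_node_samples[i])}
            return {"leaf": False, "threshold": float(t.threshold[i]),
                    "n": int(t.n_node_samples[i]),
                    "left": node(t.children_left[i]),
                    "right": node(t.children_right[i])}

        return {"ccp_alpha": self.ccp_alpha_, "root": node(0)}

    def to_text(self, measure: str = "x") -> str:
        def fmt(nd: dict, indent: int) -> list[str]:
            pad = "  " * indent
            if nd["leaf"]:
                return [f"{pad}-> group {nd['class']} (n={nd['n']})"]
            out = [f"{pad}if {measure} <= {nd['threshold']:.4g} (n={nd['n']}):"]
            out += fmt(nd["left"], indent + 1)
            out += [f"{pad}else:"]
            out += fmt(nd["right"], indent + 1)
            return out

        return "\n".join(fmt(self.to_dict()["root"], 0))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def fit_cart(values, labels, params: CARTParams = CARTParams(),
             seed: int | None = None) -> SurrogateTreeClassifier:
    """Fit the constrained, CV-pruned univariate CART."""
    return SurrogateTreeClassifier(
        min_split=params.min_split, min_leaf=params.min_leaf,
        max_depth=params.max_depth, cv_folds=params.cv_folds,
        random_state=seed).fit(values, labels)


@dataclass
class ConfusionMatrix:
    """k x k counts: rows = tree-estimated group, columns = cluster label."""

    counts: np.ndarray
    classes: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"G{c}" for c in self.classes],
                            columns=[f"C{c}" for c in self.classes])


def evaluate(tree: SurrogateTreeClassifier, values, labels) -> ConfusionMatrix:
    """Confusion matrix of tree estimates (rows) against cluster labels."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty evaluation partition")
    pred = tree.predict(values)
    classes = sorted(set(np.unique(labels)) | set(tree.classes_))
    lut = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(pred, labels):
        counts[lut[p], lut[t]] += 1
    return ConfusionMatrix(counts, classes)


def accuracy(cm: ConfusionMatrix) -> float:
    """Correctly classified fraction: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def select_best_measure(measure_matrix: pd.DataFrame, labels: pd.Series,
                        split: DataSplit, params: CARTParams = CARTParams(),
                        seed: int | None = None):
    """Train one tree per measure; keep the best on the validation partition.

    Returns ``(measure, validation_accuracies, fitted_trees)``; accuracy
    ties break toward the earlier measure in A..E order. With an empty
    validation partition (e.g. a 70/0/30 protocol) selection falls back to
    training accuracy, with a warning.
    """
    train_ids, val_ids = list(split.train), list(split.validation)
    if not val_ids:
        logger.warning("empty validation partition; selecting on training accuracy")
        val_ids = train_ids
    accs: dict[str, float] = {}
    trees: dict[str, SurrogateTreeClassifier] = {}
    for m in MEASURE_NAMES:
        if m not in measure_matrix.columns:
            continue
        t_seed = None if seed is None else derive_seed(seed, f"cart:{m}")
        tree = fit_cart(measure_matrix.loc[train_ids, m].to_numpy(),
                        labels.loc[train_ids].to_numpy(), params, seed=t_seed)
        cm = evaluate(tree, measure_matrix.loc[val_ids, m].to_numpy(),
                      labels.loc[val_ids].to_numpy())
        trees[m], accs[m] = tree, accuracy(cm)
    best = max(accs, key=lambda m: (accs[m], -MEASURE_NAMES.index(m)))
    return best, accs, trees
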