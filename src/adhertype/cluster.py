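"""k-means typology with bootstrap Jaccard stability.

The cluster count is chosen from the within-group sum-of-squares (WSS)
curve over k = 1..15: the automated stand-in for visual scree inspection
takes the interior point at maximal perpendicular distance from the chord
joining the curve's endpoints after min-max normalising both axes (a manual
override is honoured).

Stability is assessed by re-clustering bootstrap resamples: each original
cluster, restricted to the patients present in the resample, is matched to
the resample cluster with the highest Jaccard similarity. A replicate with
best-match Jaccard below 0.5 counts as a *dissolution* of that cluster.
The scaling regime whose full chain (scale -> PCA -> k -> clusters) yields
the most stable clusters wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from ._rng import derive_seed
from .latent import SCALING_METHODS, AdherencePCA, MeasureScaler, PCAResult

__all__ = [
    "ClusterSolution",
    "WSSCurve",
    "StabilityReport",
    "ScalingEvaluation",
    "ClusterTypology",
    "kmeans_fit",
    "wss_curve",
    "select_k_elbow",
    "jaccard",
    "bootstrap_stability",
    "select_scaling",
    "order_clusters",
]


@dataclass
class ClusterSolution:
    k: int
    labels: pd.Series          # cluster id per patient
    centroids: np.ndarray      # k x d
    wss_total: float
    n_init: int

    def members(self, cluster) -> set:
        return set(self.labels.index[self.labels == cluster])


@dataclass
class WSSCurve:
    ks: np.ndarray
    wss: np.ndarray


@dataclass
class StabilityReport:
    """Per-cluster bootstrap stability of one clustering solution."""

    clusters: list
    mean_jaccard: np.ndarray
    dissolution_rate: np.ndarray
    n_bootstrap: int
    scaling_method: str | None = None

    @property
    def overall_mean_jaccard(self) -> float:
        return float(np.mean(self.mean_jaccard))

    @property
    def overall_dissolution(self) -> float:
        return float(np.mean(self.dissolution_rate))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": self.clusters,
            "mean_jaccard": self.mean_jaccard,
            "dissolution_rate": self.dissolution_rate,
            "n_bootstrap": self.n_bootstrap,
            "scaling_method": self.scaling_method,
        })


def _scores_array(scores) -> tuple[np.ndarray, pd.Index]:
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=float), scores.index
    arr = np.asarray(scores, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, pd.RangeIndex(arr.shape[0])


def kmeans_fit(scores, k: int, n_init: int = 25,
               seed: int | None = None) -> ClusterSolution:
    """Best-of-``n_init`` k-means solution, deterministic given the seed."""
    arr, index = _scores_array(scores)
    n_distinct = np.unique(arr, axis=0).shape[0]
    if not 1 <= k <= n_distinct:
        raise ValueError(f"k={k} must lie in [1, {n_distinct}] (distinct points)")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(arr)
    return ClusterSolution(k=k, labels=pd.Series(labels, index=index),
                           centroids=km.cluster_centers_,
                           wss_total=float(km.inertia_), n_init=n_init)


def wss_curve(scores, k_range=range(1, 16), n_init: int = 25,
              seed: int | None = None) -> WSSCurve:
    arr, _ = _scores_array(scores)
    n_distinct = np.unique(arr, axis=0).shape[0]
    ks = np.asarray(sorted(k_range), dtype=int)
    # beyond the number of distinct points every point owns a centroid,
    # so the WSS is exactly that of k = n_distinct (namely 0)
    wss = np.array([
        kmeans_fit(scores, int(min(k, n_distinct)), n_init=n_init,
                   seed=None if seed is None else derive_seed(seed, f"k={k}")
                   ).wss_total
        for k in ks])
    return WSSCurve(ks=ks, wss=wss)


def select_k_elbow(curve: WSSCurve, override: int | None = None) -> int:
    """Elbow of the WSS curve by the maximal-chord-distance rule.

    Both axes are min-max normalised, the chord joins the first and last
    curve points, and the interior point farthest from the chord wins (ties
    broken toward smaller k). A flat curve returns k=1 with a warning.
    """
    if override is not None:
        return int(override)
    if len(curve.ks) < 3:
        raise ValueError("at least three points required on the WSS curve")
    wss = np.asarray(curve.wss, dtype=float)
    span = wss.max() - wss.min()
    if span <= 1e-12 * max(1.0, abs(wss.max())):
        warnings.warn("flat WSS curve; returning k=1")
        return int(curve.ks[0])
    x = (curve.ks - curve.ks[0]) / (curve.ks[-1] - curve.ks[0])
    y = (wss - wss.min()) / span
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    pts = np.column_stack([x, y]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0])
    interior = dist[1:-1]
    if interior.max() <= 1e-12:
        warnings.warn("degenerate (linear) WSS curve; elbow ill-defined, "
                      "taking the smallest interior k")
        return int(curve.ks[1])
    return int(curve.ks[1 + int(np.argmax(interior))])


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|, with 0 for two empty sets."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def bootstrap_stability(scores, k: int, n_bootstrap: int = 1000,
                        n_init: int = 25, seed: int | None = None,
                        dissolution_threshold: float = 0.5,
                        solution: ClusterSolution | None = None,
                        ) -> StabilityReport:
    """Bootstrap Jaccard stability of the full-sample k-means solution.

    Each replicate resamples patients with replacement, re-clusters the
    resample, and scores every original cluster (restricted to the unique
    patients present in the resample) by its best Jaccard match among the
    resample clusters.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be at least 1")
    arr, index = _scores_array(scores)
    n = arr.shape[0]
    if solution is None:
        solution = kmeans_fit(scores, k, n_init=n_init,
                              seed=None if seed is None
                              else derive_seed(seed, "full-sample"))
    clusters = sorted(pd.unique(solution.labels))
    orig_sets = [set(np.flatnonzero(solution.labels.to_numpy() == c))
                 for c in clusters]

    rng = np.random.default_rng(seed)
    jac = np.zeros((n_bootstrap, len(clusters)))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        km_seed = int(rng.integers(0, 2**31))
        km = KMeans(n_clusters=k, n_init=n_init, random_state=km_seed)
        boot_labels = km.fit_predict(arr[idx])
        present = np.unique(idx)
        # unique original index -> bootstrap cluster (duplicates agree)
        first_pos = {i: p for p, i in reversed(list(enumerate(idx)))}
        boot_sets = [set() for _ in range(k)]
        for i in present:
            boot_sets[boot_labels[first_pos[i]]].add(int(i))
        present_set = set(int(i) for i in present)
        for ci, orig in enumerate(orig_sets):
            restricted = orig & present_set
            jac[b, ci] = max(jaccard(restricted, bs) for bs in boot_sets)

    return StabilityReport(
        clusters=list(clusters),
        mean_jaccard=jac.mean(axis=0),
        dissolution_rate=(jac < dissolution_threshold).mean(axis=0),
        n_bootstrap=n_bootstrap,
    )


@dataclass
class ScalingEvaluation:
    """One scaling regime's full chain: PCA, chosen k, solution, stability."""

    method: str
    scaler: MeasureScaler
    pca: PCAResult
    curve: WSSCurve
    k: int
    solution: ClusterSolution
    stability: StabilityReport


def select_scaling(measure_matrix, methods=SCALING_METHODS, *,
                   variance_threshold: float = 0.95,
                   k_range=range(1, 16), k_override: int | None = None,
                   n_init: int = 25, n_bootstrap: int = 1000,
                   dissolution_threshold: float = 0.5,
                   seed: int | None = None,
                   ) -> tuple[ScalingEvaluation, dict[str, ScalingEvaluation]]:
    """Run the full chain per scaling regime; keep the most stable clusters.

    The winner maximises the mean of per-cluster mean Jaccard similarities;
    ties break toward lower mean dissolution rate, then toward the earlier
    method in ``methods``.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("at least one scaling method required")
    evaluations: dict[str, ScalingEvaluation] = {}
    for method in methods:
        pca_est = AdherencePCA(variance_threshold)
        scaler = MeasureScaler(method=method).fit(measure_matrix)
        scaled = scaler.transform(measure_matrix)
        pca = pca_est.fit(scaled).result_()
        scores = pca.scores.iloc[:, :pca.n_components_95]
        sub = None if seed is None else derive_seed(seed, f"scaling:{method}")
        n = scores.shape[0]
        ks = [k for k in k_range if k <= n - 1] or [1]
        curve = wss_curve(scores, ks, n_init=n_init, seed=sub)
        k = select_k_elbow(curve, override=k_override)
        solution = kmeans_fit(scores, k, n_init=n_init,
                              seed=None if sub is None
                              else derive_seed(sub, "full-sample"))
        stability = bootstrap_stability(
            scores, k, n_bootstrap=n_bootstrap, n_init=n_init,
            seed=sub, dissolution_threshold=dissolution_threshold,
            solution=solution)
        stability.scaling_method = method
        evaluations[method] = ScalingEvaluation(
            method, scaler, pca, curve, k, solution, stability)

    best = max(
        methods,
        key=lambda m: (evaluations[m].stability.overall_mean_jaccard,
                       -evaluations[m].stability.overall_dissolution,
                       -methods.index(m)))
    return evaluations[best], evaluations


def order_clusters(solution: ClusterSolution,
                   measure_a: pd.Series) -> ClusterSolution:
    """Renumber clusters 1..k by ascending within-cluster median of measure A.

    Cluster 1 is therefore the poorest-adherence group. Median ties break by
    cluster size, descending.
    """
    labels = solution.labels
    stats = []
    for c in sorted(pd.unique(labels)):
        ids = labels.index[labels == c]
        stats.append((float(measure_a.loc[ids].median()), -len(ids), c))
    mapping = {c: rank + 1 for rank, (_, _, c) in enumerate(sorted(stats))}
    order = sorted(mapping, key=mapping.get)
    return ClusterSolution(
        k=solution.k,
        labels=labels.map(mapping),
        centroids=solution.centroids[np.array(order)],
        wss_total=solution.wss_total,
        n_init=solution.n_init)


class ClusterTypology(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper: WSS-curve k selection plus final k-means fit.

    Parameters mirror the protocol defaults: 25 random initiations, k
    searched over 1..15 (``k`` pins the count and skips the elbow rule).
    """

    def __init__(self, k: int | None = None, k_max: int = 15,
                 n_init: int = 25, random_state: int | None = None):
        self.k = k
        self.k_max = k_max
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        arr, index = _scores_array(X)
        ks = [k for k in range(1, self.k_max + 1) if k <= arr.shape[0] - 1] or [1]
        self.wss_curve_ = wss_curve(pd.DataFrame(arr, index=index), ks,
                                    n_init=self.n_init, seed=self.random_state)
        self.k_ = select_k_elbow(self.wss_curve_, override=self.k)
        self.solution_ = kmeans_fit(
            pd.DataFrame(arr, index=index), self.k_, n_init=self.n_init,
            seed=None if self.random_state is None
            else derive_seed(self.random_state, "full-sample"))
        self.labels_ = self.solution_.labels.to_numpy()
        return self

    def bootstrap_stability(self, X, n_bootstrap: int = 1000,
                            dissolution_threshold: float = 0.5) -> StabilityReport:
        return bootstrap_stability(
            X, self.k_, n_bootstrap=n_bootstrap, n_init=self.n_init,
            seed=self.random_state, dissolution_threshold=dissolution_threshold,
            solution=self.solution_)
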