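"""Scaling regimes and PCA over the five-measure matrix.

The adherence measures live on different effective scales (A-C are
percentages, D and E are rates per 100 days), and principal components are
sensitive to scale. Three pre-processing regimes are compared: zero-centering
only, unit-variance standardisation, and min-max scaling to [0, 1]. The
component count retained downstream is the smallest number explaining at
least 95% of total variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "SCALING_METHODS",
    "MeasureScaler",
    "PCAResult",
    "AdherencePCA",
    "scale_measures",
    "fit_pca",
    "select_components",
]

SCALING_METHODS = ("center_only", "unit_variance", "min_max")


class MeasureScaler(BaseEstimator, TransformerMixin):
    """Column-wise scaler with the three regimes used before PCA.

    Parameters
    ----------
    method : {"center_only", "unit_variance", "min_max"}
    variance_divisor : {"sd", "variance"}
        Under ``unit_variance``, divide centred columns by the standard
        deviation (conventional) or by the variance. Population (ddof=0)
        moments are used either way.
    """

    def __init__(self, method: str = "unit_variance",
                 variance_divisor: str = "sd"):
        self.method = method
        self.variance_divisor = variance_divisor

    def fit(self, X, y=None):
        if self.method not in SCALING_METHODS:
            raise ValueError(f"unknown scaling method {self.method!r}")
        if self.variance_divisor not in ("sd", "variance"):
            raise ValueError("variance_divisor must be 'sd' or 'variance'")
        X, cols = _as_array(X)
        if X.shape[0] < 2:
            raise ValueError("at least two rows required to fit a scaler")
        if np.isnan(X).any():
            raise ValueError("missing entries are not allowed")
        self.feature_names_in_ = cols
        self.mean_ = X.mean(axis=0)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        if self.method == "center_only":
            self.offset_, self.scale_ = self.mean_, np.ones(X.shape[1])
        elif self.method == "unit_variance":
            var = X.var(axis=0)
            self._check_spread(var, cols, "zero-spread")
            self.offset_ = self.mean_
            self.scale_ = np.sqrt(var) if self.variance_divisor == "sd" else var
        else:  # min_max
            spread = self.data_max_ - self.data_min_
            self._check_spread(spread, cols, "constant")
            self.offset_, self.scale_ = self.data_min_, spread
        return self

    @staticmethod
    def _check_spread(spread, cols, word):
        bad = np.flatnonzero(spread == 0)
        if bad.size:
            names = [cols[j] if cols is not None else j for j in bad]
            raise ValueError(f"{word} column(s) cannot be scaled: {names}")

    def transform(self, X):
        arr, cols = _as_array(X)
        out = (arr - self.offset_) / self.scale_
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    def inverse_transform(self, X):
        arr, _ = _as_array(X)
        return arr * self.scale_ + self.offset_


def _as_array(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def scale_measures(matrix, method: str, **kwargs):
    """Scale the measure matrix; returns (scaled matrix, fitted scaler)."""
    scaler = MeasureScaler(method=method, **kwargs).fit(matrix)
    return scaler.transform(matrix), scaler


@dataclass
class PCAResult:
    """PCA over the scaled measure matrix.

    ``loadings`` is the orthonormal eigenvector basis (variables x
    components); ``correlations`` holds the variable-component correlation
    coefficients, the +/-1-bounded quantities reported in loading tables.
    Components are sign-fixed so that the first variable (measure A) loads
    non-negatively on each.
    """

    loadings: pd.DataFrame
    correlations: pd.DataFrame
    variance_explained: np.ndarray
    scores: pd.DataFrame
    n_components_95: int

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_explained)


class AdherencePCA(BaseEstimator, TransformerMixin):
    """PCA wrapper retaining the components that meet the variance rule.

    ``transform`` returns the scores of the first ``n_components_95_``
    components — the coordinates clustering consumes.
    """

    def __init__(self, variance_threshold: float = 0.95):
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        arr, cols = _as_array(X)
        n, p = arr.shape
        if n < 2:
            raise ValueError("at least two rows required for PCA")
        self._pca = PCA(n_components=min(n, p), svd_solver="full")
        scores = self._pca.fit_transform(arr)
        m = self._pca.n_components_

        basis = self._pca.components_.T.copy()  # p x m, orthonormal columns
        # deterministic sign: first (nonzero) variable loads non-negatively
        for j in range(m):
            col = basis[:, j]
            nz = np.flatnonzero(np.abs(col) > 1e-12)
            if nz.size and col[nz[0]] < 0:
                basis[:, j] *= -1
                scores[:, j] *= -1

        ratio = np.zeros(p)
        ratio[:m] = self._pca.explained_variance_ratio_

        # variable-component correlations (0 where either side is constant)
        corr = np.zeros((p, m))
        xs = arr - arr.mean(axis=0)
        xsd = xs.std(axis=0)
        ssd = scores.std(axis=0)
        for j in range(m):
            if ssd[j] > 1e-12:
                ok = xsd > 1e-12
                corr[ok, j] = (xs[:, ok].T @ scores[:, j]) / (n * xsd[ok] * ssd[j])

        var_names = cols if cols is not None else [f"var{i+1}" for i in range(p)]
        comp_names = [f"PC{i+1}" for i in range(m)]
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)

        self.loadings_ = pd.DataFrame(basis, index=var_names, columns=comp_names)
        self.correlations_ = pd.DataFrame(corr, index=var_names, columns=comp_names)
        self.variance_explained_ = ratio
        self.scores_ = pd.DataFrame(scores, index=index, columns=comp_names)
        self.n_components_95_ = select_components_from_fractions(
            ratio, self.variance_threshold)
        return self

    def transform(self, X):
        arr, _ = _as_array(X)
        scores = (arr - self._pca.mean_) @ self.loadings_.to_numpy()
        out = scores[:, :self.n_components_95_]
        cols = self.loadings_.columns[:self.n_components_95_]
        index = X.index if isinstance(X, pd.DataFrame) else None
        return pd.DataFrame(out, index=index, columns=cols)

    def result_(self) -> PCAResult:
        return PCAResult(self.loadings_, self.correlations_,
                         self.variance_explained_, self.scores_,
                         self.n_components_95_)


def fit_pca(scaled_matrix, variance_threshold: float = 0.95) -> PCAResult:
    """Run PCA on an already-scaled (centred) measure matrix."""
    return AdherencePCA(variance_threshold).fit(scaled_matrix).result_()


def select_components_from_fractions(fractions, threshold: float = 0.95) -> int:
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(np.asarray(fractions, dtype=float))
    meets = np.flatnonzero(cum >= threshold - 1e-12)
    if meets.size == 0:
        warnings.warn("cumulative variance never reaches the threshold; "
                      "retaining all components")
        return len(cum)
    return int(meets[0]) + 1


def select_components(result: PCAResult, threshold: float = 0.95) -> int:
    """Smallest component count whose cumulative variance meets the rule."""
    return select_components_from_fractions(result.variance_explained, threshold)
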