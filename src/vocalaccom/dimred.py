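"""Standardization, correlation-matrix PCA, and parallel-analysis retention.

Components are retained when their eigenvalue exceeds the 95% quantile of the
corresponding eigenvalue rank across many standard-normal datasets of the same
shape (Horn's parallel analysis).  Retention stops at the first rank that
fails, so the retained set is always the leading run of components.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NoComponentsRetainedError",
    "parallel_analysis_thresholds",
    "ParallelAnalysisPCA",
    "zscore_fit_apply",
    "fit_retain",
    "project",
]


class NoComponentsRetainedError(ValueError):
    """No eigenvalue exceeded its parallel-analysis threshold.

    The retention rule is undefined in this case; callers should either
    lower the quantile, supply explicit thresholds, or treat the data as
    structureless.
    """


def _corr_eigvals(z: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the sample correlation matrix of z-scores."""
    n = z.shape[0]
    c = (z.T @ z) / (n - 1)
    vals = np.linalg.eigvalsh(c)
    return vals[::-1]


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return (x - mu) / sd


def parallel_analysis_thresholds(
    n_rows: int,
    n_cols: int,
    n_iter: int = 10000,
    quantile: float = 0.95,
    seed: int | None = None,
    mode: str = "rankwise",
) -> np.ndarray:
    """Per-rank eigenvalue thresholds from random standard-normal data.

    For each of ``n_iter`` datasets of shape (n_rows, n_cols), the
    eigenvalues of the sample correlation matrix are computed; the threshold
    for rank r is the ``quantile`` of the r-th largest eigenvalue
    (``mode="rankwise"``, classic Horn).  ``mode="scalar"`` instead pools all
    eigenvalues and applies one quantile to every rank.
    """
    if not n_rows > n_cols >= 2:
        raise ValueError("need n_rows > n_cols >= 2")
    if n_iter < 100:
        warnings.warn("n_iter < 100 gives unstable parallel-analysis quantiles")
    rng = np.random.default_rng(seed)
    eig = np.empty((n_iter, n_cols))
    for i in range(n_iter):
        x = rng.standard_normal((n_rows, n_cols))
        eig[i] = _corr_eigvals(_zscore(x))
    if mode == "rankwise":
        return np.quantile(eig, quantile, axis=0)
    if mode == "scalar":
        t = float(np.quantile(eig, quantile))
        return np.full(n_cols, t)
    raise ValueError(f"unknown mode {mode!r}")


class ParallelAnalysisPCA(TransformerMixin, BaseEstimator):
    """PCA on z-scored data with parallel-analysis component retention.

    Parameters
    ----------
    n_iter : int
        Number of random datasets for the threshold quantiles.
    quantile : float
        Quantile of the random eigenvalue distribution (0.95).
    mode : {"rankwise", "scalar"}
        Rank-wise Horn comparison (default) or a single pooled threshold.
    thresholds : array-like, optional
        Precomputed thresholds; skips the random-data simulation (useful when
        many datasets share one shape).
    random_state : int, optional
        Seed for the threshold simulation.

    Attributes
    ----------
    mean_, scale_ : per-parameter z-scaling constants (sample SD, ddof=1)
    eigenvalues_ : all correlation-matrix eigenvalues, descending
    explained_variance_ratio_ : eigenvalues / n_features
    thresholds_ : the per-rank retention thresholds used
    n_retained_ : number of retained components (leading run)
    components_ : (n_retained, n_features) orthonormal loadings; the
        largest-magnitude loading of each component is positive
    feature_names_in_ : column names when fitted on a DataFrame
    """

    def __init__(
        self,
        n_iter: int = 10000,
        quantile: float = 0.95,
        mode: str = "rankwise",
        thresholds=None,
        random_state: int | None = None,
    ):
        self.n_iter = n_iter
        self.quantile = quantile
        self.mode = mode
        self.thresholds = thresholds
        self.random_state = random_state

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-D")
        return arr

    def fit(self, X, y=None):
        arr = self._validate(X)
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        n, p = arr.shape
        if n < 2:
            raise ValueError("need at least 2 rows")
        sd = arr.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = np.nonzero(sd == 0)[0]
            names = (
                [str(self.feature_names_in_[i]) for i in bad]
                if hasattr(self, "feature_names_in_")
                else [str(i) for i in bad]
            )
            raise ValueError(f"constant column(s): {', '.join(names)}")
        self.mean_ = arr.mean(axis=0)
        self.scale_ = sd
        z = (arr - self.mean_) / self.scale_

        # correlation-matrix PCA via SVD of the z-scores
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eigvals = s**2 / (n - 1)
        self.eigenvalues_ = eigvals
        self.explained_variance_ratio_ = eigvals / p

        if self.thresholds is not None:
            thr = np.asarray(self.thresholds, dtype=float)
            if thr.shape != (p,):
                raise ValueError("thresholds length must equal n_features")
        else:
            thr = parallel_analysis_thresholds(
                n, p, self.n_iter, self.quantile, self.random_state, self.mode
            )
        self.thresholds_ = thr

        exceeds = eigvals > thr
        k = 0
        while k < p and exceeds[k]:
            k += 1
        if k == 0:
            raise NoComponentsRetainedError(
                "no eigenvalue exceeds its parallel-analysis threshold; "
                "the data shows no retainable structure at this quantile"
            )
        comps = vt[:k]
        # deterministic sign: largest-|loading| entry positive per component
        for row in comps:
            j = int(np.argmax(np.abs(row)))
            if row[j] < 0:
                row *= -1
        self.n_retained_ = k
        self.components_ = comps
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValueError(f"missing column(s): {', '.join(map(str, missing))}")
            X = X[list(self.feature_names_in_)]
        arr = self._validate(X)
        z = (arr - self.mean_) / self.scale_
        return z @ self.components_.T

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        check_is_fitted(self, "components_")
        payload = {
            "format": "vocalaccom.RetainedPCModel",
            "version": 1,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "thresholds": self.thresholds_.tolist(),
            "n_retained": int(self.n_retained_),
            "components": self.components_.tolist(),
            "feature_names": (
                [str(c) for c in self.feature_names_in_]
                if hasattr(self, "feature_names_in_")
                else None
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ParallelAnalysisPCA":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "vocalaccom.RetainedPCModel":
            raise ValueError("not a serialized RetainedPCModel")
        model = cls()
        model.mean_ = np.asarray(d["mean"])
        model.scale_ = np.asarray(d["scale"])
        model.eigenvalues_ = np.asarray(d["eigenvalues"])
        model.explained_variance_ratio_ = np.asarray(d["explained_variance_ratio"])
        model.thresholds_ = np.asarray(d["thresholds"])
        model.n_retained_ = int(d["n_retained"])
        model.components_ = np.asarray(d["components"])
        if d.get("feature_names"):
            model.feature_names_in_ = np.asarray(d["feature_names"], dtype=object)
        return model


# -- thin functional wrappers ---------------------------------------------


def zscore_fit_apply(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-transform every column (sample SD); returns (z-table, means, SDs)."""
    means = table.mean()
    sds = table.std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0].tolist()
        raise ValueError(f"constant column(s): {', '.join(map(str, bad))}")
    return (table - means) / sds, means, sds


def fit_retain(
    table: pd.DataFrame, thresholds=None, n_iter: int = 10000, seed: int | None = None
) -> ParallelAnalysisPCA:
    """Fit a :class:`ParallelAnalysisPCA` on a feature table."""
    return ParallelAnalysisPCA(n_iter=n_iter, thresholds=thresholds, random_state=seed).fit(table)


def project(model: ParallelAnalysisPCA, table: pd.DataFrame) -> np.ndarray:
    """Project a table onto the retained components (z-scale, then loadings)."""
    return model.transform(table)
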