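"""Vocal distance: calls vs a population's average vocalization.

A population's average vocalization is the centroid, in retained-PC space, of
the baseline individuals' 10% trimmed means along each component axis.  Each
call's vocal distance is the Euclidean norm of its score offset from that
centroid after every axis has been multiplied by the proportion of total
variance its component explains; distances are ln-transformed for modeling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PopulationCentroid",
    "trimmed_mean",
    "population_centroid",
    "weighted_distance",
    "build_distance_records",
    "VocalDistance",
    "LN_FLOOR",
]

#: distances of exactly zero are clamped here before the ln transform
LN_FLOOR = 1e-12


@dataclass
class PopulationCentroid:
    """Average vocalization of a population in retained-PC space."""

    call_type: str | None
    coordinates: np.ndarray
    individual_ids: tuple[str, ...]
    trim: float = 0.10

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.individual_ids) < 2:
            raise ValueError("a population centroid needs >= 2 contributing individuals")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "call_type": self.call_type,
                    "coordinates": self.coordinates.tolist(),
                    "individual_ids": list(self.individual_ids),
                    "trim": self.trim,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "PopulationCentroid":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            call_type=d["call_type"],
            coordinates=np.asarray(d["coordinates"]),
            individual_ids=tuple(d["individual_ids"]),
            trim=d["trim"],
        )


def trimmed_mean(values, trim: float = 0.10) -> float:
    """Mean after dropping floor(trim*n) smallest and largest values."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty input")
    k = int(np.floor(trim * v.size))
    kept = v[k : v.size - k]
    if kept.size == 0:
        raise ValueError("no values left after trimming")
    return float(np.mean(kept))


def population_centroid(
    scores: pd.DataFrame,
    pc_cols: list[str] | None = None,
    *,
    individual_col: str = "caller_id",
    call_type: str | None = None,
    trim: float = 0.10,
) -> PopulationCentroid:
    """Two-stage centroid: per-individual trimmed means, then their mean.

    Along each retained component axis, every baseline individual's 10%
    trimmed mean is computed first; the centroid coordinate is the unweighted
    mean of those per-individual values, so each animal contributes equally
    regardless of how many calls it gave.
    """
    if pc_cols is None:
        pc_cols = [c for c in scores.columns if str(c).startswith("PC")]
    ids = tuple(sorted(scores[individual_col].unique()))
    if len(ids) < 2:
        raise ValueError("need >= 2 baseline individuals for a centroid")
    per_ind = np.array(
        [
            [trimmed_mean(grp[c].to_numpy(), trim) for c in pc_cols]
            for _, grp in scores.groupby(individual_col, sort=True)
        ]
    )
    return PopulationCentroid(
        call_type=call_type,
        coordinates=per_ind.mean(axis=0),
        individual_ids=ids,
        trim=trim,
    )


def weighted_distance(
    score,
    centroid,
    proportions,
    mode: str = "scale",
) -> float:
    """Variance-weighted Euclidean distance from a call to the centroid.

    ``mode="scale"`` (default): each axis difference is multiplied by its
    component's explained-variance proportion before the Euclidean norm,
    ``d = sqrt(sum_k (p_k * (s_k - c_k))^2)``.  ``mode="sqrt"`` uses the
    proportions as inner-product weights, ``d = sqrt(sum_k p_k (s_k-c_k)^2)``
    — exposed for sensitivity analysis.
    """
    s = np.asarray(score, dtype=float)
    c = centroid.coordinates if isinstance(centroid, PopulationCentroid) else np.asarray(centroid, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if s.shape != c.shape or s.shape != p.shape:
        raise ValueError(
            f"dimension mismatch: score {s.shape}, centroid {c.shape}, proportions {p.shape}"
        )
    diff = s - c
    if mode == "scale":
        return float(np.sqrt(np.sum((p * diff) ** 2)))
    if mode == "sqrt":
        return float(np.sqrt(np.sum(p * diff**2)))
    raise ValueError(f"unknown mode {mode!r}")


class VocalDistance(TransformerMixin, BaseEstimator):
    """Distance-to-population transformer.

    ``fit(X, groups=...)`` learns the population centroid from baseline
    scores (per-individual trimmed means averaged across individuals);
    ``transform(X)`` maps call scores to their weighted distances.

    Parameters
    ----------
    proportions : array-like
        Explained-variance proportions of the retained components (of the
        *total* variance, i.e. eigenvalue / n_parameters).
    trim : float
        Trim fraction for the per-individual means (0.10).
    mode : {"scale", "sqrt"}
        Weighting convention, see :func:`weighted_distance`.
    """

    def __init__(self, proportions=None, trim: float = 0.10, mode: str = "scale"):
        self.proportions = proportions
        self.trim = trim
        self.mode = mode

    def fit(self, X, y=None, *, groups=None):
        X = np.asarray(X, dtype=float)
        if groups is None:
            raise ValueError("fit requires groups= (baseline individual labels)")
        groups = np.asarray(groups)
        ids = np.unique(groups)
        if ids.size < 2:
            raise ValueError("need >= 2 baseline individuals")
        per_ind = np.array(
            [
                [trimmed_mean(X[groups == g, j], self.trim) for j in range(X.shape[1])]
                for g in ids
            ]
        )
        self.centroid_ = PopulationCentroid(
            call_type=None,
            coordinates=per_ind.mean(axis=0),
            individual_ids=tuple(str(g) for g in ids),
            trim=self.trim,
        )
        p = np.asarray(
            self.proportions if self.proportions is not None else np.ones(X.shape[1]),
            dtype=float,
        )
        if p.shape != (X.shape[1],):
            raise ValueError("proportions length must equal n_components")
        self.proportions_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "centroid_")
        X = np.asarray(X, dtype=float)
        diff = X - self.centroid_.coordinates
        if self.mode == "scale":
            d = np.sqrt(np.sum((self.proportions_ * diff) ** 2, axis=1))
        elif self.mode == "sqrt":
            d = np.sqrt(np.sum(self.proportions_ * diff**2, axis=1))
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        return d


def build_distance_records(
    scores: pd.DataFrame,
    centroid: PopulationCentroid,
    proportions,
    *,
    pc_cols: list[str] | None = None,
    mode: str = "scale",
) -> pd.DataFrame:
    """One distance record per call, with the ln transform applied.

    Keeps the caller/sex/call-type/week/condition metadata needed by the
    accommodation models.  Distances of exactly zero (probability zero for
    real data) are clamped at a tiny floor before taking logs, with a
    warning.
    """
    if pc_cols is None:
        pc_cols = [c for c in scores.columns if str(c).startswith("PC")]
    X = scores[pc_cols].to_numpy(dtype=float)
    p = np.asarray(proportions, dtype=float)
    if X.shape[1] != centroid.coordinates.size or X.shape[1] != p.size:
        raise ValueError("score / centroid / proportions dimension mismatch")
    diff = X - centroid.coordinates
    if mode == "scale":
        d = np.sqrt(np.sum((p * diff) ** 2, axis=1))
    elif mode == "sqrt":
        d = np.sqrt(np.sum(p * diff**2, axis=1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(d == 0):
        warnings.warn("zero vocal distance encountered; clamping before ln transform")
        d = np.maximum(d, LN_FLOOR)
    meta = [c for c in ["caller_id", "sex", "call_type", "week", "condition"] if c in scores.columns]
    out = scores[meta].copy()
    out["distance"] = d
    out["ln_distance"] = np.log(d)
    return out
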