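"""Crossed permuted discriminant function analysis (pDFA).

Tests whether calls differ between conditions (the *test factor*) while
controlling for individual identity (the *control factor*).  The statistic is
the mean percentage of held-out calls correctly cross-classified by a Fisher
linear discriminant derived from balanced training subsets; its null
distribution comes from restricted permutations that relabel whole
(individual x condition) blocks of calls within each individual, so that the
non-independence of calls from one animal is never broken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["PDFADesign", "PDFAResult", "lda_fit_classify", "CrossedPDFA", "crossed_pdfa"]


@dataclass
class PDFADesign:
    """Configuration of one crossed pDFA run."""

    test_factor: str = "condition"
    control_factor: str = "caller_id"
    variables: list[str] | None = None  # default: all PC* columns
    n_permutations: int = 1000
    n_selection_rounds: int = 100
    cell_quota: int | None = None  # default: min cell size - 1, at least 2
    seed: int | None = None


@dataclass
class PDFAResult:
    """Observed vs chance-expected cross-classification and permutation p."""

    pct_expected_correct: float
    pct_actual_correct: float
    p_value: float
    n_calls: int
    n_individuals: int
    n_permutations_used: int

    @property
    def trend(self) -> bool:
        """p < 0.1 — reported as a trend, as in the source analyses."""
        return self.p_value < 0.1


def _pooled_cov(X: np.ndarray, y: np.ndarray, classes: np.ndarray):
    """Class means and pooled within-class covariance (ddof = n - K)."""
    p = X.shape[1]
    means = np.empty((classes.size, p))
    s = X.T @ X
    n = X.shape[0]
    for k, c in enumerate(classes):
        xk = X[y == c]
        mk = xk.mean(axis=0)
        means[k] = mk
        s -= xk.shape[0] * np.outer(mk, mk)
    cov = s / (n - classes.size)
    return means, cov


def lda_fit_classify(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    ridge: float | None = None,
) -> np.ndarray:
    """Fisher linear discriminant with pooled within-class covariance.

    Classes get equal priors; ties break toward the first class in sorted
    label order (``argmax`` over sorted classes).  A near-singular pooled
    covariance falls back to a small ridge (1e-8 x trace/p on the diagonal).
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    p = X_train.shape[1]
    for c in classes:
        if np.sum(y_train == c) < p + 1:
            raise ValueError(f"class {c!r} has fewer than n_variables+1 training rows")
    means, cov = _pooled_cov(X_train, y_train, classes)
    lam = ridge if ridge is not None else 0.0
    try:
        w = np.linalg.solve(cov + lam * np.eye(p), means.T)
    except np.linalg.LinAlgError:
        lam = 1e-8 * np.trace(cov) / p
        w = np.linalg.solve(cov + lam * np.eye(p), means.T)
    # linear discriminant scores, equal priors
    scores = X_test @ w - 0.5 * np.sum(means.T * w, axis=0)
    return classes[np.argmax(scores, axis=1)]


class CrossedPDFA(BaseEstimator):
    """Crossed pDFA as a fit-shaped estimator.

    ``fit(X, y, groups)`` runs the full permutation test: X is the
    (n_calls, n_variables) score matrix, ``y`` the test-factor labels and
    ``groups`` the control-factor (individual) labels.  Every individual
    must appear in every condition (crossed design).

    For each of ``n_selection_rounds`` balanced splits, ``cell_quota`` calls
    per (individual x condition) cell train the discriminant and the
    remaining calls are classified; the statistic is the mean held-out
    percent correct.  The same selection-averaged statistic is recomputed on
    ``n_permutations`` datasets whose condition labels are permuted across
    whole blocks within each individual.  The p-value uses the add-one
    convention; the chance-expected percent correct is the mean of the
    permuted statistics.
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        n_selection_rounds: int = 100,
        cell_quota: int | None = None,
        random_state: int | None = None,
    ):
        self.n_permutations = n_permutations
        self.n_selection_rounds = n_selection_rounds
        self.cell_quota = cell_quota
        self.random_state = random_state

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = np.asarray(groups)
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        conds = np.unique(y)
        inds = np.unique(groups)
        if conds.size < 2:
            raise ValueError("need at least 2 test-factor levels")

        # (individual x condition) cells, row index arrays
        cells: list[np.ndarray] = []
        cell_group: list[int] = []
        cell_cond: list[int] = []
        for gi, g in enumerate(inds):
            for ci, c in enumerate(conds):
                idx = np.nonzero((groups == g) & (y == c))[0]
                if idx.size == 0:
                    raise ValueError(
                        f"design not crossed: individual {g!r} has no calls "
                        f"in condition {c!r}"
                    )
                cells.append(idx)
                cell_group.append(gi)
                cell_cond.append(ci)
        sizes = np.array([c.size for c in cells])
        min_cell = int(sizes.min())
        quota = self.cell_quota if self.cell_quota is not None else max(2, min_cell - 1)
        if quota > min_cell:
            raise ValueError(
                f"cell_quota {quota} exceeds the smallest cell size {min_cell}"
            )
        if not np.any(sizes > quota):
            raise ValueError("no held-out calls: every cell equals the quota")

        rng = np.random.default_rng(self.random_state)
        cell_cond = np.array(cell_cond)
        cell_group_arr = np.array(cell_group)

        observed = self._mean_holdout_pct(X, cells, sizes, cell_cond, conds, quota, rng)
        null = np.empty(self.n_permutations)
        n_cells_per_ind = conds.size
        for b in range(self.n_permutations):
            permuted = cell_cond.copy()
            for gi in range(inds.size):
                mask = cell_group_arr == gi
                permuted[mask] = permuted[mask][rng.permutation(n_cells_per_ind)]
            null[b] = self._mean_holdout_pct(X, cells, sizes, permuted, conds, quota, rng)

        self.pct_actual_correct_ = float(observed)
        self.pct_expected_correct_ = float(np.mean(null))
        self.p_value_ = float((np.sum(null >= observed) + 1) / (self.n_permutations + 1))
        self.null_distribution_ = null
        self.n_calls_ = int(X.shape[0])
        self.n_individuals_ = int(inds.size)
        self.n_permutations_used_ = int(self.n_permutations)
        self.cell_quota_ = int(quota)
        return self

    def _mean_holdout_pct(self, X, cells, sizes, cell_cond, conds, quota, rng):
        """Mean held-out percent correct over the selection rounds."""
        n_rounds = self.n_selection_rounds
        n_classes = conds.size
        p = X.shape[1]
        # pregenerate per-cell selection orders for all rounds at once
        orders = [
            np.argsort(rng.random((n_rounds, s)), axis=1) if s > 1 else np.zeros((n_rounds, 1), int)
            for s in sizes
        ]
        train_labels = np.repeat(cell_cond, quota)
        test_labels = np.concatenate(
            [np.full(s - quota, c) for s, c in zip(sizes, cell_cond)]
        )
        n_test = test_labels.size
        class_counts = np.bincount(train_labels, minlength=n_classes).astype(float)
        acc = 0.0
        eye = np.eye(p)
        for r in range(n_rounds):
            train_idx = np.concatenate(
                [cell[o[r, :quota]] for cell, o in zip(cells, orders)]
            )
            test_idx = np.concatenate(
                [cell[o[r, quota:]] for cell, o in zip(cells, orders) if o.shape[1] > quota]
            )
            Xtr = X[train_idx]
            Xte = X[test_idx]
            # class means via index add (labels are 0..K-1)
            sums = np.zeros((n_classes, p))
            np.add.at(sums, train_labels, Xtr)
            means = sums / class_counts[:, None]
            s = Xtr.T @ Xtr - (means.T * class_counts) @ means
            cov = s / (Xtr.shape[0] - n_classes)
            try:
                w = np.linalg.solve(cov, means.T)
            except np.linalg.LinAlgError:
                lam = 1e-8 * np.trace(cov) / p
                w = np.linalg.solve(cov + lam * eye, means.T)
            scores = Xte @ w - 0.5 * np.sum(means.T * w, axis=0)
            pred = np.argmax(scores, axis=1)
            acc += np.mean(pred == test_labels)
        return 100.0 * acc / n_rounds


def crossed_pdfa(scores: pd.DataFrame, design: PDFADesign) -> PDFAResult:
    """Run a crossed pDFA on a scores table with metadata columns."""
    variables = design.variables
    if variables is None:
        variables = [c for c in scores.columns if str(c).startswith("PC")]
    if not variables:
        raise ValueError("no score variables found (expected PC* columns)")
    est = CrossedPDFA(
        n_permutations=design.n_permutations,
        n_selection_rounds=design.n_selection_rounds,
        cell_quota=design.cell_quota,
        random_state=design.seed,
    ).fit(
        scores[variables].to_numpy(dtype=float),
        scores[design.test_factor].to_numpy(),
        scores[design.control_factor].to_numpy(),
    )
    return PDFAResult(
        pct_expected_correct=est.pct_expected_correct_,
        pct_actual_correct=est.pct_actual_correct_,
        p_value=est.p_value_,
        n_calls=est.n_calls_,
        n_individuals=est.n_individuals_,
        n_permutations_used=est.n_permutations_used_,
    )
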