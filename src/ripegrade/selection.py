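"""Quadratic sequential forward feature selection.

Greedy forward selection over the 285-feature registry: at each step the
candidate feature that minimizes the stratified k-fold cross-validated
QDA misclassification rate of the augmented subset is added; selection
stops when no candidate strictly improves the criterion (or at
``max_features``).  Features are z-scored on each training fold before
the QDA fit.  Fold assignment is derived from a canonical row order
(class, then image id), so selection is invariant to row shuffling of
the table; candidate ties break by registry column order.
"""
from __future__ import annotations

import difflib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import StratifiedKFold

from .discriminant import fit_gaussian_params, gaussian_log_posterior
from .features import FEATURE_NAMES, feature_columns

#: The 16 features reported optimal on the original fruit images,
#: usable as a fixed subset when selection is skipped.
OPTIMUM_FEATURES: tuple[str, ...] = (
    "mean_B",
    "skewness_Lstar", "kurtosis_Lstar",
    "mean_bstar",
    "mean_nr",
    "mean_ng", "skewness_ng",
    "mean_nb",
    "mean_I2",
    "mean_I3", "kurtosis_I3",
    "mean_cr",
    "mean_cb", "skewness_cb",
    "mean_H", "mean_S",
)


@dataclass
class SelectionTrace:
    """Accepted steps (feature, criterion) of one forward-selection run."""

    steps: list[tuple[str, float]]
    selected: list[str]
    criterion: str = "qda_cv_error"
    cv_folds: int = 5
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "criterion": self.criterion, "cv_folds": self.cv_folds,
            "seed": self.seed, "selected": self.selected,
            "steps": [{"feature": f, "criterion_value": v} for f, v in self.steps],
        }, indent=2)


def resolve_feature_names(names) -> list[int]:
    """Map canonical feature names to registry column indices."""
    lut = {name: i for i, name in enumerate(FEATURE_NAMES)}
    out = []
    for name in names:
        if name not in lut:
            close = difflib.get_close_matches(name, FEATURE_NAMES, n=3)
            raise KeyError(f"unknown feature name {name!r}; did you mean {close}?")
        out.append(lut[name])
    return out


def _canonical_folds(table: pd.DataFrame, cv_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds assigned on a canonical (class, image_id) row order."""
    n = len(table)
    if "image_id" in table.columns:
        order = np.lexsort((table["image_id"].to_numpy(), table["class"].to_numpy()))
    else:
        order = np.lexsort((np.arange(n), table["class"].to_numpy()))
    y_sorted = table["class"].to_numpy()[order]
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(np.zeros(n), y_sorted):
        folds.append((order[tr], order[te]))
    return folds


def _qda_cv_error(X: np.ndarray, y_idx: np.ndarray, n_classes: int,
                  cols: list[int], folds, reg: float) -> float:
    """Stratified-CV QDA misclassification rate on the given columns."""
    errors = 0
    total = 0
    Xc = X[:, cols]
    for tr, te in folds:
        Xtr, Xte = Xc[tr], Xc[te]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        means, covs, priors = fit_gaussian_params(
            (Xtr - mu) / sd, y_idx[tr], n_classes, kind="qda", reg=reg)
        scores = gaussian_log_posterior((Xte - mu) / sd, means, covs, priors)
        errors += int(np.sum(np.argmax(scores, axis=1) != y_idx[te]))
        total += len(te)
    return errors / total


def sfs_quadratic(
    table: pd.DataFrame,
    max_features: int | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    reg: float = 1e-6,
) -> SelectionTrace:
    """Forward feature selection with a cross-validated QDA error criterion.

    Requires every class to have at least ``cv_folds`` samples.  Returns
    the accepted steps and the final ordered subset; the criterion value
    is strictly decreasing over accepted steps.
    """
    cols = feature_columns(table)
    y = table["class"].to_numpy()
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < cv_folds:
        raise ValueError(
            f"every class needs >= cv_folds={cv_folds} samples "
            f"(smallest has {counts.min()})")
    X = table[cols].to_numpy(dtype=float)
    folds = _canonical_folds(table, cv_folds, seed)

    selected: list[int] = []
    steps: list[tuple[str, float]] = []
    best = np.inf
    limit = max_features if max_features is not None else len(cols)
    while len(selected) < limit:
        cand_best: tuple[float, int] | None = None
        for ci in range(len(cols)):
            if ci in selected:
                continue
            err = _qda_cv_error(X, y_idx, len(classes), selected + [ci], folds, reg)
            if cand_best is None or err < cand_best[0]:
                cand_best = (err, ci)
        if cand_best is None or cand_best[0] >= best:
            break
        best, ci = cand_best
        selected.append(ci)
        steps.append((cols[ci], best))
    return SelectionTrace(
        steps=steps, selected=[cols[i] for i in selected],
        cv_folds=cv_folds, seed=seed)


class SequentialQdaSelector(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`sfs_quadratic`.

    Fit on a feature table (DataFrame with a ``class`` column, or X/y
    arrays); ``transform`` keeps only the selected columns.
    """

    def __init__(self, max_features=None, cv_folds=5, seed=0, reg=1e-6):
        self.max_features = max_features
        self.cv_folds = cv_folds
        self.seed = seed
        self.reg = reg

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame) and "class" in X.columns:
            table = X
        else:
            X = np.asarray(X, dtype=float)
            if y is None:
                raise ValueError("y is required when X is a plain array")
            table = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
            table["class"] = np.asarray(y)
        self.trace_ = sfs_quadratic(
            table, max_features=self.max_features, cv_folds=self.cv_folds,
            seed=self.seed, reg=self.reg)
        self.selected_ = list(self.trace_.selected)
        cols = feature_columns(table)
        self.support_ = np.array([c in set(self.selected_) for c in cols])
        self._columns = cols
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.selected_]
        return np.asarray(X, dtype=float)[:, self.support_]

    def get_support(self) -> np.ndarray:
        return self.support_
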