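"""Linear and quadratic discriminant classifiers and the 80:20 protocol.

Both classifiers fit Gaussian class-conditional densities: LDA pools the
within-class covariance, QDA keeps one covariance per class.  Features
are z-scored on the training data by default (the raw features span
scales from ~1e-4 to >20), and a small ridge is added to any covariance
whose smallest eigenvalue falls below 1e-8.  Prediction is the argmax of
the Gaussian log-posterior; exact ties go to the class earliest in the
display order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_array, check_is_fitted

from .classes import CLASS_ORDER


@dataclass(frozen=True)
class SplitConfig:
    """Stratified random split ratios; (0.8, 0.2) or (0.6, 0.2, 0.2)."""

    ratios: tuple[float, ...] = (0.8, 0.2)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ratios) not in (2, 3) or min(self.ratios) <= 0:
            raise ValueError("ratios must be 2 or 3 positive numbers")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


def split_indices(labels, cfg: SplitConfig) -> tuple[np.ndarray, ...]:
    """Index arrays for the train/test (or train/val/test) split."""
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    strat = labels if cfg.stratified else None
    if len(cfg.ratios) == 2:
        tr, te = train_test_split(
            idx, test_size=cfg.ratios[1], stratify=strat, random_state=cfg.seed)
        return np.sort(tr), np.sort(te)
    rest, te = train_test_split(
        idx, test_size=cfg.ratios[2], stratify=strat, random_state=cfg.seed)
    val_frac = cfg.ratios[1] / (cfg.ratios[0] + cfg.ratios[1])
    strat_rest = labels[rest] if cfg.stratified else None
    tr, va = train_test_split(
        rest, test_size=val_frac, stratify=strat_rest, random_state=cfg.seed + 1)
    return np.sort(tr), np.sort(va), np.sort(te)


# ---------------------------------------------------------------------------
# Gaussian core (shared with the sequential feature selector)

def _regularize(cov: np.ndarray, reg: float) -> np.ndarray:
    d = cov.shape[0]
    if np.linalg.eigvalsh(cov).min() < 1e-8:
        cov = cov + reg * np.eye(d)
        if np.linalg.eigvalsh(cov).min() < 1e-12:
            raise np.linalg.LinAlgError(
                "singular covariance; set reg > 0 to regularize")
    return cov


def fit_gaussian_params(X, y_idx, n_classes, kind="lda", reg=1e-6, priors=None):
    """Class means, covariance(s), priors for LDA ('lda') or QDA ('qda')."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    means = np.zeros((n_classes, d))
    counts = np.zeros(n_classes)
    covs = []
    pooled = np.zeros((d, d))
    for c in range(n_classes):
        Xc = X[y_idx == c]
        if len(Xc) < 2:
            raise ValueError(f"class index {c} has fewer than 2 training samples")
        counts[c] = len(Xc)
        means[c] = Xc.mean(axis=0)
        dev = Xc - means[c]
        scatter = dev.T @ dev
        pooled += scatter
        covs.append(scatter / (len(Xc) - 1))
    pooled /= (n - n_classes)
    if priors is None:
        priors = counts / counts.sum()
    else:
        priors = np.asarray(priors, dtype=float)
        if abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
    if kind == "lda":
        covs = [_regularize(pooled, reg)] * n_classes
    elif kind == "qda":
        covs = [_regularize(c, reg) for c in covs]
    else:
        raise ValueError("kind must be 'lda' or 'qda'")
    return means, covs, priors


def gaussian_log_posterior(X, means, covs, priors) -> np.ndarray:
    """Unnormalized log-posterior scores, one column per class."""
    X = np.asarray(X, dtype=float)
    n_classes = len(means)
    scores = np.zeros((X.shape[0], n_classes))
    for c in range(n_classes):
        cov = covs[c]
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("covariance is not positive definite")
        dev = X - means[c]
        maha = np.einsum("ij,ij->i", dev @ np.linalg.inv(cov), dev)
        scores[:, c] = -0.5 * (logdet + maha) + np.log(priors[c])
    return scores


# ---------------------------------------------------------------------------

class DiscriminantClassifier(ClassifierMixin, BaseEstimator):
    """Gaussian discriminant classifier (LDA or QDA).

    Parameters
    ----------
    kind : {"lda", "qda"}
        Pooled covariance (linear boundaries) or per-class covariances
        (quadratic boundaries).
    reg : float
        Ridge added to a covariance whose smallest eigenvalue is < 1e-8;
        with ``standardize=True`` this acts on the correlation scale.
    priors : array-like or None
        Class priors; ``None`` uses empirical class frequencies.
    standardize : bool
        z-score features on the training data before fitting.
    class_order : sequence or None
        Fixed label order for ties/one-hot; ``None`` uses the canonical
        ripeness display order when labels allow it, else sorted labels.
    """

    def __init__(self, kind="lda", reg=1e-6, priors=None, standardize=True,
                 class_order=None):
        self.kind = kind
        self.reg = reg
        self.priors = priors
        self.standardize = standardize
        self.class_order = class_order

    def _resolve_classes(self, y) -> np.ndarray:
        present = set(np.asarray(y).tolist())
        if self.class_order is not None:
            order = [c for c in self.class_order if c in present]
        elif present <= set(CLASS_ORDER):
            order = [c for c in CLASS_ORDER if c in present]
        else:
            order = sorted(present)
        return np.asarray(order)

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns)
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = self._resolve_classes(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        lut = {c: i for i, c in enumerate(self.classes_.tolist())}
        y_idx = np.array([lut[v] for v in y.tolist()])

        if self.standardize:
            self.scale_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_sd_ = np.where(sd > 0, sd, 1.0)
        else:
            self.scale_mean_ = np.zeros(X.shape[1])
            self.scale_sd_ = np.ones(X.shape[1])
        Xs = (X - self.scale_mean_) / self.scale_sd_

        means, covs, priors = fit_gaussian_params(
            Xs, y_idx, len(self.classes_), kind=self.kind, reg=self.reg,
            priors=self.priors)
        self.means_ = means
        self.priors_ = priors
        if self.kind == "lda":
            self.covariance_ = covs[0]
        else:
            self.covariances_ = covs
        self._covs = covs
        return self

    def _check_X(self, X):
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature(s): {missing}")
            X = X[list(self.feature_names_in_)]
        X = check_array(X, dtype=float)
        if X.shape[1] != self.means_.shape[1]:
            raise ValueError(
                f"expected {self.means_.shape[1]} features, got {X.shape[1]}")
        return X

    def decision_function(self, X) -> np.ndarray:
        """Per-class Gaussian log-posterior scores (unnormalized)."""
        check_is_fitted(self, "means_")
        Xs = (self._check_X(X) - self.scale_mean_) / self.scale_sd_
        return gaussian_log_posterior(Xs, self.means_, self._covs, self.priors_)

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_function(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        s = self.decision_function(X)
        return self.classes_[np.argmax(s, axis=1)]  # ties -> earliest class

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "means_")
        return {
            "kind": self.kind,
            "classes": self.classes_.tolist(),
            "means": self.means_.tolist(),
            "covariances": [c.tolist() for c in self._covs],
            "priors": self.priors_.tolist(),
            "scale_mean": self.scale_mean_.tolist(),
            "scale_sd": self.scale_sd_.tolist(),
            "feature_subset": (self.feature_names_in_.tolist()
                               if hasattr(self, "feature_names_in_") else None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantClassifier":
        model = cls(kind=d["kind"])
        model.classes_ = np.asarray(d["classes"])
        model.means_ = np.asarray(d["means"], dtype=float)
        model._covs = [np.asarray(c, dtype=float) for c in d["covariances"]]
        if d["kind"] == "lda":
            model.covariance_ = model._covs[0]
        else:
            model.covariances_ = model._covs
        model.priors_ = np.asarray(d["priors"], dtype=float)
        model.scale_mean_ = np.asarray(d["scale_mean"], dtype=float)
        model.scale_sd_ = np.asarray(d["scale_sd"], dtype=float)
        if d.get("feature_subset"):
            model.feature_names_in_ = np.asarray(d["feature_subset"])
        return model

    @classmethod
    def from_parameters(cls, kind, classes, means, covariances, priors,
                        scale_mean=None, scale_sd=None) -> "DiscriminantClassifier":
        """Build a fitted model directly from Gaussian parameters."""
        means = np.asarray(means, dtype=float)
        d = means.shape[1]
        scale_mean = np.zeros(d) if scale_mean is None else np.asarray(scale_mean)
        scale_sd = np.ones(d) if scale_sd is None else np.asarray(scale_sd)
        return cls.from_dict({
            "kind": kind,
            "classes": list(classes),
            "means": means.tolist(),
            "covariances": [np.asarray(c, dtype=float).tolist() for c in covariances],
            "priors": list(priors),
            "scale_mean": scale_mean.tolist(),
            "scale_sd": scale_sd.tolist(),
            "feature_subset": None,
        })


def fit_discriminant(table: pd.DataFrame, subset, kind="lda", reg=1e-6,
                     priors=None) -> DiscriminantClassifier:
    """Fit an LDA/QDA model on the named feature subset of a feature table."""
    model = DiscriminantClassifier(kind=kind, reg=reg, priors=priors)
    return model.fit(table[list(subset)], table["class"].to_numpy())


def predict_discriminant(model: DiscriminantClassifier, features):
    """Predict one sample; returns (class label, per-class score dict)."""
    if isinstance(features, (pd.Series, dict)):
        features = pd.DataFrame([features])
    scores = model.decision_function(features)
    label = model.classes_[int(np.argmax(scores[0]))]
    return label, dict(zip(model.classes_.tolist(), scores[0].tolist()))
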