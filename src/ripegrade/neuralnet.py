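"""Single-hidden-layer neural network classifier and structure scan.

Architecture: n selected features -> h tanh ("tangent sigmoid") hidden
units (h in 2..20) -> 4 linear outputs trained against one-hot class
membership targets by mean-squared error.  Inputs are min-max scaled to
[-1, 1] per feature (the standard companion of tanh units).  Training is
full-batch gradient descent with a backtracking line search (each epoch
strictly decreases the training MSE or training stops), early stopping
on validation MSE with a patience counter, and restoration of the
best-validation-epoch weights.  Fully deterministic given the seed.

The structure scan trains one network per hidden-layer width and reports
the validation MSE, the test-set correlation coefficient and the
whole-dataset correct classification rate for each; the optimum is the
highest CCR, then highest test correlation, then lowest validation MSE.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .classes import CLASS_ORDER
from .discriminant import SplitConfig, split_indices
from .evaluate import output_correlation


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop settings for the shallow network."""

    max_epochs: int = 400
    early_stop_patience: int = 6
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


class ShallowNetClassifier(ClassifierMixin, BaseEstimator):
    """One-hidden-layer tanh network with linear outputs (MSE training)."""

    def __init__(self, n_hidden=10, max_epochs=400, early_stop_patience=6,
                 learning_rate=0.1, random_state=0, class_order=None):
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.class_order = class_order

    # -- internals ----------------------------------------------------------

    def _resolve_classes(self, y) -> np.ndarray:
        present = set(np.asarray(y).tolist())
        if self.class_order is not None:
            order = [c for c in self.class_order if c in present]
        elif present <= set(CLASS_ORDER):
            order = [c for c in CLASS_ORDER if c in present]
        else:
            order = sorted(present)
        return np.asarray(order)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = self.in_max_ - self.in_min_
        span = np.where(span > 0, span, 1.0)
        return 2.0 * (X - self.in_min_) / span - 1.0

    def _one_hot(self, y) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes_.tolist())}
        T = np.zeros((len(y), len(self.classes_)))
        T[np.arange(len(y)), [lut[v] for v in np.asarray(y).tolist()]] = 1.0
        return T

    @staticmethod
    def _forward(Xs, W1, b1, W2, b2):
        Z = np.tanh(Xs @ W1 + b1)
        return Z, Z @ W2 + b2

    @staticmethod
    def _mse(Y, T) -> float:
        return float(np.mean((Y - T) ** 2))

    def _grad(self, Xs, T, W1, b1, W2, b2):
        n = Xs.shape[0]
        Z, Y = self._forward(Xs, W1, b1, W2, b2)
        dY = 2.0 * (Y - T) / Y.size
        gW2 = Z.T @ dY
        gb2 = dY.sum(axis=0)
        dZ = (dY @ W2.T) * (1.0 - Z ** 2)
        gW1 = Xs.T @ dZ
        gb1 = dZ.sum(axis=0)
        return gW1, gb1, gW2, gb2

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns)
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = self._resolve_classes(y)
        self.in_min_ = X.min(axis=0)
        self.in_max_ = X.max(axis=0)
        Xs = self._scale(X)
        T = self._one_hot(y)

        if validation_data is not None:
            Xv, yv = validation_data
            if isinstance(Xv, pd.DataFrame):
                Xv = Xv.to_numpy(dtype=float)
            Xvs = self._scale(np.asarray(Xv, dtype=float))
            Tv = self._one_hot(yv)
        else:
            Xvs, Tv = Xs, T  # monitor the training set itself

        rng = np.random.default_rng(self.random_state)
        d, h, k = X.shape[1], self.n_hidden, T.shape[1]
        W1 = rng.uniform(-1, 1, size=(d, h)) / np.sqrt(d)
        b1 = np.zeros(h)
        W2 = rng.uniform(-1, 1, size=(h, k)) / np.sqrt(h)
        b2 = np.zeros(k)

        lr = float(self.learning_rate)
        train_hist: list[float] = []
        val_hist: list[float] = []
        loss = self._mse(self._forward(Xs, W1, b1, W2, b2)[1], T)
        best_val = np.inf
        best_weights = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
        best_epoch = -1
        stall = 0
        for epoch in range(self.max_epochs):
            g = self._grad(Xs, T, W1, b1, W2, b2)
            accepted = False
            while lr > 1e-12:
                cand = (W1 - lr * g[0], b1 - lr * g[1],
                        W2 - lr * g[2], b2 - lr * g[3])
                cand_loss = self._mse(self._forward(Xs, *cand)[1], T)
                if not np.isfinite(cand_loss):
                    raise RuntimeError("diverged; reduce step size")
                if cand_loss < loss:
                    W1, b1, W2, b2 = cand
                    loss = cand_loss
                    lr *= 1.2
                    accepted = True
                    break
                lr *= 0.5
            if not accepted:
                break  # no descent direction at machine precision
            val_loss = self._mse(self._forward(Xvs, W1, b1, W2, b2)[1], Tv)
            train_hist.append(loss)
            val_hist.append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_weights = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
                if stall >= self.early_stop_patience:
                    break

        self.W1_, self.b1_, self.W2_, self.b2_ = best_weights
        self.history_ = {"train_mse": np.array(train_hist),
                         "val_mse": np.array(val_hist)}
        self.best_epoch_ = best_epoch
        self.validation_mse_ = float(best_val) if np.isfinite(best_val) else np.nan
        self.n_iter_ = len(train_hist)
        return self

    def decision_function(self, X) -> np.ndarray:
        """The 4 continuous (linear) outputs per sample."""
        check_is_fitted(self, "W1_")
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            X = X[list(self.feature_names_in_)]
        X = check_array(X, dtype=float)
        if X.shape[1] != self.W1_.shape[0]:
            raise ValueError(
                f"expected {self.W1_.shape[0]} features, got {X.shape[1]}")
        return self._forward(self._scale(X), self.W1_, self.b1_,
                             self.W2_, self.b2_)[1]

    def predict(self, X):
        out = self.decision_function(X)
        return self.classes_[np.argmax(out, axis=1)]  # ties -> earliest class

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "W1_")
        return {
            "n_hidden": self.n_hidden,
            "classes": self.classes_.tolist(),
            "W1": self.W1_.tolist(), "b1": self.b1_.tolist(),
            "W2": self.W2_.tolist(), "b2": self.b2_.tolist(),
            "in_min": self.in_min_.tolist(), "in_max": self.in_max_.tolist(),
            "seed": self.random_state,
            "feature_subset": (self.feature_names_in_.tolist()
                               if hasattr(self, "feature_names_in_") else None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShallowNetClassifier":
        model = cls(n_hidden=d["n_hidden"], random_state=d.get("seed", 0))
        model.classes_ = np.asarray(d["classes"])
        model.W1_ = np.asarray(d["W1"], dtype=float)
        model.b1_ = np.asarray(d["b1"], dtype=float)
        model.W2_ = np.asarray(d["W2"], dtype=float)
        model.b2_ = np.asarray(d["b2"], dtype=float)
        model.in_min_ = np.asarray(d["in_min"], dtype=float)
        model.in_max_ = np.asarray(d["in_max"], dtype=float)
        if d.get("feature_subset"):
            model.feature_names_in_ = np.asarray(d["feature_subset"])
        return model

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def train_ann(
    table: pd.DataFrame,
    subset,
    n_hidden: int,
    split: SplitConfig = SplitConfig(ratios=(0.6, 0.2, 0.2)),
    cfg: TrainConfig = TrainConfig(),
) -> tuple[ShallowNetClassifier, dict]:
    """Train one network on a 60:20:20 stratified split of the table.

    Returns the fitted model and a dict with the split index arrays and
    the per-epoch history.
    """
    if not 2 <= n_hidden <= 20:
        raise ValueError("n_hidden must be in [2, 20]")
    if len(split.ratios) != 3:
        raise ValueError("ANN protocol needs a (train, val, test) split")
    tr, va, te = split_indices(table["class"].to_numpy(), split)
    X = table[list(subset)]
    y = table["class"].to_numpy()
    model = ShallowNetClassifier(
        n_hidden=n_hidden, max_epochs=cfg.max_epochs,
        early_stop_patience=cfg.early_stop_patience,
        learning_rate=cfg.learning_rate, random_state=cfg.seed)
    model.fit(X.iloc[tr], y[tr], validation_data=(X.iloc[va], y[va]))
    info = {"train_idx": tr, "val_idx": va, "test_idx": te,
            "history": model.history_}
    return model, info


@dataclass
class StructureScanReport:
    """Per-width performance table of the hidden-neuron scan."""

    table: pd.DataFrame  # structure, n_hidden, validation_mse, test_r, ccr_all
    optimum_n_hidden: int
    models: dict[int, ShallowNetClassifier]

    @property
    def best_model(self) -> ShallowNetClassifier:
        return self.models[self.optimum_n_hidden]


def scan_structures(
    table: pd.DataFrame,
    subset,
    hidden_range=range(2, 21),
    split: SplitConfig = SplitConfig(ratios=(0.6, 0.2, 0.2)),
    cfg: TrainConfig = TrainConfig(),
) -> StructureScanReport:
    """Train networks for every hidden width and tabulate the three metrics.

    Columns mirror the scan protocol: validation-set MSE (best epoch),
    test-set correlation coefficient of outputs vs one-hot targets, and
    whole-dataset CCR.  All widths share the same split; each width gets
    its own deterministic weight seed derived from ``cfg.seed``.
    """
    hidden_range = list(hidden_range)
    if not hidden_range:
        raise ValueError("empty hidden range")
    y = table["class"].to_numpy()
    X = table[list(subset)]
    tr, va, te = split_indices(y, split)
    rows = []
    models: dict[int, ShallowNetClassifier] = {}
    for h in hidden_range:
        seed_h = int(np.random.SeedSequence([cfg.seed, h]).generate_state(1)[0]
                     % (2 ** 31))
        model = ShallowNetClassifier(
            n_hidden=h, max_epochs=cfg.max_epochs,
            early_stop_patience=cfg.early_stop_patience,
            learning_rate=cfg.learning_rate, random_state=seed_h)
        model.fit(X.iloc[tr], y[tr], validation_data=(X.iloc[va], y[va]))
        models[h] = model
        out_te = model.decision_function(X.iloc[te])
        r_te = output_correlation(model._one_hot(y[te]), out_te)
        ccr_all = 100.0 * float(np.mean(model.predict(X) == y))
        ccr_te = 100.0 * float(np.mean(model.predict(X.iloc[te]) == y[te]))
        rows.append({
            "structure": f"{X.shape[1]}-{h}-{len(model.classes_)}",
            "n_hidden": h,
            "validation_mse": model.validation_mse_,
            "test_r": r_te,
            "ccr_all": ccr_all,
            "ccr_test": ccr_te,
        })
    report = pd.DataFrame(rows)
    order = report.sort_values(
        ["ccr_all", "test_r", "validation_mse"],
        ascending=[False, False, True], kind="stable")
    best = int(order.iloc[0]["n_hidden"])
    return StructureScanReport(table=report, optimum_n_hidden=best, models=models)
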