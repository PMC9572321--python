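"""Evaluation metrics: confusion matrix, CCR, MSE, correlation.

Two distinct "MSE" notions coexist in this grading protocol and are kept
separate here: for hard classifiers (LDA/QDA) the reported MSE is the
misclassification fraction, exactly ``1 - CCR/100``; for the network,
``output_mse`` is the mean squared difference between the continuous
outputs and the one-hot membership targets (the quantity monitored on
the validation set).  The correlation coefficient is the Pearson r
between flattened one-hot targets and flattened continuous outputs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classes import CLASS_ORDER


def confusion(actual, predicted, classes=CLASS_ORDER) -> pd.DataFrame:
    """Confusion matrix, rows = actual, columns = predicted, display order."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if len(actual) != len(predicted) or len(actual) == 0:
        raise ValueError("actual and predicted must have equal nonzero length")
    classes = list(classes)
    unknown = set(actual.tolist()) | set(predicted.tolist())
    unknown -= set(classes)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual.tolist(), predicted.tolist()):
        cm[lut[a], lut[p]] += 1
    return pd.DataFrame(cm, index=classes, columns=classes)


def _as_counts(cm) -> np.ndarray:
    counts = cm.to_numpy() if isinstance(cm, pd.DataFrame) else np.asarray(cm)
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    if (counts < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    return counts


def ccr(cm) -> float:
    """Correct classification rate in percent: 100 * trace / total."""
    counts = _as_counts(cm)
    return 100.0 * float(np.trace(counts)) / float(counts.sum())


def classifier_mse(cm) -> float:
    """Misclassification fraction (the hard-classifier 'MSE')."""
    counts = _as_counts(cm)
    return float(counts.sum() - np.trace(counts)) / float(counts.sum())


def output_mse(targets, outputs) -> float:
    """Mean squared one-hot output error over all entries."""
    t = np.asarray(targets, dtype=float)
    o = np.asarray(outputs, dtype=float)
    if t.shape != o.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {o.shape}")
    return float(np.mean((o - t) ** 2))


def output_correlation(targets, outputs) -> float:
    """Pearson r between flattened one-hot targets and continuous outputs."""
    t = np.asarray(targets, dtype=float).ravel()
    o = np.asarray(outputs, dtype=float).ravel()
    if t.shape != o.shape:
        raise ValueError("targets and outputs must have equal length")
    if np.std(t) == 0 or np.std(o) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(t, o)[0])


@dataclass
class EvaluationReport:
    """One classifier's evaluation on a chosen scope of the data."""

    confusion: pd.DataFrame
    ccr: float
    mse: float
    r: float | None = None
    scope: str = "all_data"  # "all_data" | "test_only"

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "ccr": self.ccr,
            "mse": self.mse,
            "r": self.r,
            "confusion": {
                "classes": list(self.confusion.index),
                "counts": self.confusion.to_numpy().tolist(),
            },
        }

    def __str__(self) -> str:  # human-readable report
        lines = [f"scope: {self.scope}",
                 f"CCR:   {self.ccr:.2f} %",
                 f"MSE:   {self.mse:.4f}"]
        if self.r is not None:
            lines.append(f"r:     {self.r:.4f}")
        lines.append(self.confusion.to_string())
        return "\n".join(lines)


def evaluate_classifier(model, table: pd.DataFrame, subset, scope="all_data",
                        eval_index=None) -> EvaluationReport:
    """Evaluate a fitted classifier on a feature table.

    ``eval_index`` restricts evaluation (e.g. to the test split) when
    ``scope`` is not ``all_data``.
    """
    if eval_index is not None:
        table = table.iloc[eval_index]
    y = table["class"].to_numpy()
    X = table[list(subset)]
    pred = model.predict(X)
    cm = confusion(y, pred, classes=[c for c in CLASS_ORDER if c in set(y)])
    r = None
    if hasattr(model, "decision_function") and hasattr(model, "_one_hot"):
        r = output_correlation(model._one_hot(y), model.decision_function(X))
    return EvaluationReport(confusion=cm, ccr=ccr(cm), mse=classifier_mse(cm),
                            r=r, scope=scope)
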