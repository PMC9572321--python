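"""Ripeness stage labels and their canonical display order.

The four maturity stages are graded by inspector panels; confusion
matrices, one-hot targets and per-class tables all use the fixed display
order ``overripe, ripe, secondary_unripe, initial_unripe``.
"""
from __future__ import annotations

from enum import Enum

import numpy as np


class RipenessStage(str, Enum):
    """One of the four maturity classes of a fruit sample."""

    OVERRIPE = "overripe"
    RIPE = "ripe"
    SECONDARY_UNRIPE = "secondary_unripe"
    INITIAL_UNRIPE = "initial_unripe"

    @property
    def display_index(self) -> int:
        """1-based position in the canonical display order."""
        return CLASS_ORDER.index(self.value) + 1


#: Canonical class order used for one-hot encoding and confusion-matrix axes.
CLASS_ORDER: tuple[str, ...] = tuple(s.value for s in RipenessStage)


def class_indices(labels) -> np.ndarray:
    """Map an iterable of stage labels to 0-based display-order indices."""
    lut = {name: i for i, name in enumerate(CLASS_ORDER)}
    try:
        return np.array([lut[str(RipenessStage(lab).value)] for lab in labels])
    except ValueError as exc:
        raise ValueError(f"unknown ripeness label: {exc}") from exc


def one_hot(labels) -> np.ndarray:
    """Encode stage labels as an (n, 4) membership matrix (1 = member)."""
    idx = class_indices(labels)
    out = np.zeros((len(idx), len(CLASS_ORDER)))
    out[np.arange(len(idx)), idx] = 1.0
    return out
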