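"""Fruit segmentation from a white background.

Five-step procedure: (1) binarize the gray level, (2) invert, (3) clean
with morphological opening then closing, (4) fill holes and drop small
components, keeping the largest, (5) remove the background by masking.

Binarization normalizes polarity so that the background — sampled on the
image border — maps to ``True`` before inversion; on a white-background
scene this is exactly "bright background -> True".  The polarity rule
makes the pipeline idempotent: re-segmenting an already background-
removed (black-background) image returns the same mask.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk, opening

from .channels import bt601_gray


class DegenerateHistogramError(ValueError):
    """Otsu thresholding on an all-constant image."""


class NoForegroundError(ValueError):
    """Segmentation produced no foreground component."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Segmentation parameters.

    ``min_component_area`` of ``None`` means 0.1% of the image area.
    """

    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    structuring_element_radius: int = 2
    min_component_area: int | None = None
    keep: str = "largest_component"

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if (self.threshold_method == "fixed") != (self.fixed_threshold is not None):
            raise ValueError("fixed_threshold is required iff threshold_method='fixed'")
        if self.fixed_threshold is not None and not 0 <= self.fixed_threshold <= 1:
            raise ValueError("fixed_threshold must be in [0, 1]")
        if self.structuring_element_radius < 1:
            raise ValueError("structuring_element_radius must be >= 1")

    def resolved_min_area(self, shape) -> int:
        if self.min_component_area is not None:
            return int(self.min_component_area)
        return int(round(0.001 * shape[0] * shape[1]))


@dataclass
class MaskedImage:
    """Background-free image: fruit pixels kept, background zeroed + flagged."""

    pixels: np.ndarray  # (H, W, 3), background set to 0
    mask: np.ndarray    # (H, W) bool, True = fruit


def binarize(img: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Threshold the gray level into a boolean image, background = True.

    Polarity is normalized using the border pixels (assumed background).
    """
    px = np.asarray(img, dtype=float)
    gray = bt601_gray(px) if px.ndim == 3 else px
    if cfg.threshold_method == "fixed":
        t = float(cfg.fixed_threshold)
    else:
        if np.ptp(gray) < 1e-12:
            raise DegenerateHistogramError("degenerate histogram: constant image")
        t = threshold_otsu(gray)
    binary = gray >= t
    border = np.concatenate(
        [binary[0, :], binary[-1, :], binary[1:-1, 0], binary[1:-1, -1]])
    if border.mean() < 0.5:  # dark background: flip so background is True
        binary = ~binary
    return binary


def invert(b: np.ndarray) -> np.ndarray:
    """Logical negation (involutive)."""
    return ~np.asarray(b, dtype=bool)


def morph_clean(b: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Morphological opening then closing with a disk structuring element."""
    se = disk(cfg.structuring_element_radius)
    return closing(opening(np.asarray(b, dtype=bool), se), se)


def remove_noise_fill(b: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Fill holes, drop components below the area floor, keep the largest."""
    b = np.asarray(b, dtype=bool)
    filled = binary_fill_holes(b)
    min_area = cfg.resolved_min_area(b.shape)
    lab, n = label(filled, return_num=True)
    if n == 0:
        raise NoForegroundError("no foreground found")
    areas = np.bincount(lab.ravel())[1:]
    keep = np.where(areas >= min_area)[0]
    if keep.size == 0:
        raise NoForegroundError("no foreground found")
    largest = keep[np.argmax(areas[keep])]
    return lab == (int(largest) + 1)


def apply_mask(img: np.ndarray, m: np.ndarray) -> MaskedImage:
    """Zero out background pixels; fruit pixels pass through unchanged."""
    px = np.asarray(img, dtype=float)
    m = np.asarray(m, dtype=bool)
    if px.shape[:2] != m.shape:
        raise ValueError(f"mask shape {m.shape} does not match image {px.shape[:2]}")
    if not m.any():
        raise NoForegroundError("no foreground found")
    out = np.where(m[..., None], px, 0.0)
    return MaskedImage(pixels=out, mask=m)


def preprocess_pipeline(
    img, cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[MaskedImage, np.ndarray]:
    """Run the five segmentation steps in order; returns (masked image, mask)."""
    if hasattr(img, "pixels"):
        img = img.pixels
    b = binarize(img, cfg)
    b = invert(b)
    b = morph_clean(b, cfg)
    mask = remove_noise_fill(b, cfg)
    return apply_mask(img, mask), mask
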