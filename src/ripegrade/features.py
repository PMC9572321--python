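"""Per-image feature extraction: 15 statistics x 19 channels = 285 features.

Nine first-order statistics (min, mean, max, std, cv, median, mode,
skewness, kurtosis) are computed over fruit pixels only, and six texture
features (homogeneity, covariance, contrast, correlation, entropy,
energy) are computed from a mask-aware gray-level co-occurrence matrix
(GLCM) of each channel.  Feature names are ``<statistic>_<channel>``;
column order is fixed by the registry (channels outer, statistics inner).

Conventions for degenerate inputs (all values finite by construction):
population moments; cv = std/mean with cv = 0 when the mean is 0; mode =
midpoint of the densest of 256 equal-width bins; skewness = m3/m2^1.5 and
kurtosis = m4/m2^2 (non-excess; a Gaussian gives 3), both 0 along with cv
when the variance vanishes; GLCM correlation = 1 when either marginal
deviation vanishes; entropy in bits with 0·log 0 = 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNEL_NAMES, to_channels
from .preprocess import MaskedImage

#: Statistic order within each channel block.
STAT_NAMES: tuple[str, ...] = (
    "min", "mean", "max", "std", "cv", "median", "mode", "skewness", "kurtosis",
    "homogeneity", "covariance", "contrast", "correlation", "entropy", "energy",
)

#: Canonical 285-feature registry: <statistic>_<channel>.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{ch}" for ch in CHANNEL_NAMES for stat in STAT_NAMES
)

_FIRST_ORDER = STAT_NAMES[:9]
_TEXTURE = STAT_NAMES[9:]


class DegenerateRegionError(ValueError):
    """Too few in-mask pixel pairs to form a co-occurrence matrix."""


@dataclass(frozen=True)
class GlcmConfig:
    """Co-occurrence parameters: quantization levels, pixel-pair offsets.

    Defaults: 8 gray levels over the masked min-max range, the four
    distance-1 offsets, symmetric counting, matrices averaged over
    offsets after per-offset normalization.
    """

    levels: int = 8
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(dy == 0 and dx == 0 for dy, dx in self.offsets):
            raise ValueError("offsets must be nonzero")


def first_order_stats(values: np.ndarray) -> dict[str, float]:
    """The nine first-order statistics of a nonempty sample (see module doc)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    mean = float(v.mean())
    m2 = float(np.mean((v - mean) ** 2))
    std = float(np.sqrt(m2))
    degenerate = std <= 1e-9 * (1.0 + abs(mean))
    if degenerate:
        std = cv = skew = kurt = 0.0  # constant sample up to rounding
        mode = mean
    else:
        cv = 0.0 if mean == 0 else std / mean
        m3 = float(np.mean((v - mean) ** 3))
        m4 = float(np.mean((v - mean) ** 4))
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
        counts, edges = np.histogram(v, bins=256)
        k = int(np.argmax(counts))
        mode = float((edges[k] + edges[k + 1]) / 2.0)
    return {
        "min": float(v.min()), "mean": mean, "max": float(v.max()),
        "std": std, "cv": cv, "median": float(np.median(v)),
        "mode": mode, "skewness": skew, "kurtosis": kurt,
    }


def glcm(
    channel: np.ndarray,
    mask: np.ndarray,
    cfg: GlcmConfig = GlcmConfig(),
) -> np.ndarray:
    """Mask-aware normalized gray-level co-occurrence matrix.

    The channel is quantized to ``cfg.levels`` equal-width bins over the
    masked min-max range (a constant region maps to level 0).  Only pixel
    pairs with BOTH members in-mask are counted; each offset's matrix is
    (optionally) symmetrized and normalized to sum 1, then matrices are
    averaged over offsets.
    """
    ch = np.asarray(channel, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if ch.shape != m.shape:
        raise ValueError("channel and mask shapes differ")
    vals = ch[m]
    if vals.size == 0:
        raise DegenerateRegionError("degenerate region: empty mask")
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        q = np.clip(((ch - lo) / (hi - lo) * cfg.levels).astype(int),
                    0, cfg.levels - 1)
    else:
        q = np.zeros_like(ch, dtype=int)

    h, w = ch.shape
    mats = []
    total_pairs = 0
    for dy, dx in cfg.offsets:
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        if y0 >= y1 or x0 >= x1:
            continue
        src = (slice(y0, y1), slice(x0, x1))
        dst = (slice(y0 + dy, y1 + dy), slice(x0 + dx, x1 + dx))
        valid = m[src] & m[dst]
        a = q[src][valid]
        b = q[dst][valid]
        total_pairs += a.size
        if a.size == 0:
            continue
        c = np.zeros((cfg.levels, cfg.levels))
        np.add.at(c, (a, b), 1.0)
        if cfg.symmetric:
            c = c + c.T
        mats.append(c / c.sum())
    if total_pairs < 2:
        raise DegenerateRegionError("degenerate region: fewer than 2 pixel pairs")
    return np.mean(mats, axis=0)


def texture_features(P: np.ndarray) -> dict[str, float]:
    """Six texture features of a normalized co-occurrence matrix."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if abs(P.sum() - 1.0) > 1e-8:
        raise ValueError("co-occurrence matrix must be normalized to sum 1")
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(np.sum(np.arange(n) * pi))
    mu_j = float(np.sum(np.arange(n) * pj))
    sd_i = float(np.sqrt(np.sum((np.arange(n) - mu_i) ** 2 * pi)))
    sd_j = float(np.sqrt(np.sum((np.arange(n) - mu_j) ** 2 * pj)))
    cov = float(np.sum(P * (i - mu_i) * (j - mu_j)))
    corr = 1.0 if sd_i * sd_j < 1e-15 else cov / (sd_i * sd_j)
    pos = P[P > 0]
    return {
        "homogeneity": float(np.sum(P / (1.0 + np.abs(i - j)))),
        "covariance": cov,
        "contrast": float(np.sum(P * (i - j) ** 2)),
        "correlation": corr,
        "entropy": float(-np.sum(pos * np.log2(pos))),
        "energy": float(np.sum(P ** 2)),
    }


def extract_features(
    img: MaskedImage,
    cfg: GlcmConfig = GlcmConfig(),
) -> pd.Series:
    """All 285 named features of one background-removed image."""
    if img.mask is None or np.count_nonzero(img.mask) < 2:
        raise ValueError("valid mask with >= 2 fruit pixels required")
    stack = to_channels(img)
    out: dict[str, float] = {}
    for ch in CHANNEL_NAMES:
        raster = stack[ch]
        fo = first_order_stats(raster[img.mask])
        tex = texture_features(glcm(raster, img.mask, cfg))
        for stat in _FIRST_ORDER:
            out[f"{stat}_{ch}"] = fo[stat]
        for stat in _TEXTURE:
            out[f"{stat}_{ch}"] = tex[stat]
    return pd.Series([out[name] for name in FEATURE_NAMES],
                     index=list(FEATURE_NAMES), dtype=float)


def extract_table(
    images: Sequence[MaskedImage] | Iterable,
    labels: Sequence[str],
    image_ids: Sequence[str] | None = None,
    cfg: GlcmConfig = GlcmConfig(),
) -> pd.DataFrame:
    """Feature table (rows = images) with ``image_id`` and ``class`` columns."""
    images = list(images)
    if len(images) == 0:
        raise ValueError("empty image set")
    if len(labels) != len(images):
        raise ValueError("labels length must match images")
    if image_ids is None:
        image_ids = [f"img_{k:04d}" for k in range(len(images))]
    rows = []
    for iid, img in zip(image_ids, images):
        try:
            rows.append(extract_features(img, cfg))
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for image {iid!r}: {exc}") from exc
    table = pd.DataFrame(rows).reset_index(drop=True)
    table.insert(0, "class", list(labels))
    table.insert(0, "image_id", list(image_ids))
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table (everything but image_id/class)."""
    return [c for c in table.columns if c not in ("image_id", "class")]
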