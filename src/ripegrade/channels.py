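"""Decomposition of an RGB image into 19 scalar color channels.

Six color spaces are used — RGB, CIELAB, Ohta's I1I2I3, chromaticity NRGB,
the chromatic-deviation CrCgCb, and HSV — plus the BT.601 gray level,
giving 19 named scalar rasters per image:

    R, G, B, I1, I2, I3, L*, a*, b*, nr, ng, nb, cr, cg, cb, H, S, V, gray

All channels are computed per pixel from RGB values in [0, 1].  CIELAB
assumes sRGB primaries with a D65 white point (consumer-camera images);
gray uses the BT.601 luma weights; I1I2I3 is Ohta's decorrelated space
(I1 = (R+G+B)/3, I2 = (R−B)/2, I3 = (2G−R−B)/4); NRGB is the intensity-free
chromaticity nr = R/(R+G+B) (0 where the sum is 0); CrCgCb is the signed
chromatic deviation from gray (cr = R − gray, ...).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage import color as skcolor

#: Canonical channel order; fixed for feature naming and table columns.
CHANNEL_NAMES: tuple[str, ...] = (
    "R", "G", "B",
    "I1", "I2", "I3",
    "Lstar", "astar", "bstar",
    "nr", "ng", "nb",
    "cr", "cg", "cb",
    "H", "S", "V",
    "gray",
)

#: BT.601/NTSC luma weights (full precision; printed as 0.2989/0.5870/0.1140).
#: Normalized to sum exactly 1 so chromatic deviations vanish on gray pixels.
_LUMA = np.array([0.298936021293775, 0.587043074451121, 0.114020904255103])
_LUMA = _LUMA / _LUMA.sum()


def channel_names() -> tuple[str, ...]:
    """Return the canonical ordered tuple of the 19 channel names."""
    return CHANNEL_NAMES


def bt601_gray(pixels: np.ndarray) -> np.ndarray:
    """BT.601 luma: 0.2989 R + 0.5870 G + 0.1140 B."""
    return pixels @ _LUMA


@dataclass
class ChannelStack:
    """The 19 named scalar rasters of one image plus its foreground mask."""

    channels: Mapping[str, np.ndarray]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = set(CHANNEL_NAMES) - set(self.channels)
        extra = set(self.channels) - set(CHANNEL_NAMES)
        if missing or extra:
            raise ValueError(f"channel stack must have exactly the 19 canonical "
                             f"channels; missing={sorted(missing)} extra={sorted(extra)}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def to_channels(image, mask: np.ndarray | None = None) -> ChannelStack:
    """Convert an RGB image (array or MaskedImage) into the 19-channel stack.

    Parameters
    ----------
    image : (H, W, 3) float array in [0, 1], or an object with ``pixels``
        and ``mask`` attributes (a masked image).
    mask : optional boolean (H, W) array overriding the image's own mask.

    Raises
    ------
    ValueError
        If pixel values fall outside [0, 1].
    """
    if hasattr(image, "pixels"):
        if mask is None:
            mask = getattr(image, "mask", None)
        image = image.pixels
    px = np.asarray(image, dtype=float)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {px.shape}")
    if px.min() < -1e-12 or px.max() > 1 + 1e-12:
        raise ValueError("RGB values must lie in [0, 1]")
    px = np.clip(px, 0.0, 1.0)

    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    gray = bt601_gray(px)

    i1 = (r + g + b) / 3.0
    i2 = (r - b) / 2.0
    i3 = (2.0 * g - r - b) / 4.0

    s = r + g + b
    with np.errstate(invalid="ignore", divide="ignore"):
        nr = np.where(s > 0, r / np.where(s > 0, s, 1.0), 0.0)
        ng = np.where(s > 0, g / np.where(s > 0, s, 1.0), 0.0)
        nb = np.where(s > 0, b / np.where(s > 0, s, 1.0), 0.0)

    cr, cg, cb = r - gray, g - gray, b - gray

    hsv = skcolor.rgb2hsv(px)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    hue = np.where(sat == 0.0, 0.0, hue)  # H undefined on achromatic pixels

    lab = skcolor.rgb2lab(px)  # sRGB -> XYZ (D65) -> CIELAB

    stack = {
        "R": r, "G": g, "B": b,
        "I1": i1, "I2": i2, "I3": i3,
        "Lstar": lab[..., 0], "astar": lab[..., 1], "bstar": lab[..., 2],
        "nr": nr, "ng": ng, "nb": nb,
        "cr": cr, "cg": cg, "cb": cb,
        "H": hue, "S": sat, "V": val,
        "gray": gray,
    }
    return ChannelStack(channels=stack, mask=mask)
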