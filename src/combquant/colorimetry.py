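"""Conversion between sRGB rasters and CIELAB perceptual lightness.

Uncapped comb cells are segmented on the L* ("luminance") channel of
CIELAB because it tracks human-perceived brightness: the dark cell lumen
against its bright wax wall is the highest-contrast feature on a frame
photograph regardless of camera or flash.  All conversions assume 8-bit
sRGB input with the D65 white point; L* is on the conventional 0-100
scale (0 = black, 100 = diffuse white).
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2lab

from .errors import InvalidImageError

__all__ = ["to_luminance", "luminance_to_srgb_grey"]


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to its CIELAB L* channel.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3), uint8
        Standard sRGB photograph (D65 white point assumed).

    Returns
    -------
    ndarray, shape (H, W), float64
        Per-pixel perceptual lightness L* in [0, 100].

    Raises
    ------
    InvalidImageError
        If the raster is empty or does not have exactly three channels.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise InvalidImageError(
            f"expected an (H, W, 3) RGB raster, got shape {arr.shape}"
        )
    if arr.size == 0:
        raise InvalidImageError("empty raster")
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    lab = rgb2lab(arr)
    return np.ascontiguousarray(lab[..., 0])


# CIELAB forward/inverse constants (D65, 2 degree observer)
_DELTA = 6.0 / 29.0


def luminance_to_srgb_grey(lightness: np.ndarray | float) -> np.ndarray:
    """Invert L* to the 8-bit grey level g such that L*(g, g, g) == L*.

    Used by the synthetic scene renderer so that rendered luminance
    targets survive the round trip through an sRGB-encoded image file.
    Exact inverse of the sRGB gamma + CIELAB f-function for neutral
    greys (R = G = B implies X/Xn = Y/Yn = Z/Zn).
    """
    L = np.asarray(lightness, dtype=np.float64)
    fy = (L + 16.0) / 116.0
    Y = np.where(fy > _DELTA, fy ** 3, 3.0 * _DELTA ** 2 * (fy - 4.0 / 29.0))
    srgb = np.where(
        Y <= 0.0031308,
        12.92 * Y,
        1.055 * np.power(np.clip(Y, 0.0, None), 1.0 / 2.4) - 0.055,
    )
    return np.clip(np.round(srgb * 255.0), 0, 255).astype(np.uint8)
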