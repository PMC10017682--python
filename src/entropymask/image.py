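"""Basic raster conversions shared by all maskers."""

from __future__ import annotations

import numpy as np

__all__ = ["rgb_to_gray", "as_gray"]


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit grayscale.

    Uses the ITU-R BT.601 luma weights, ``0.299 R + 0.587 G + 0.114 B``,
    rounded to the nearest integer and clamped to [0, 255] — the convention
    shared by the mainstream imaging libraries, so masks computed here line
    up with masks computed elsewhere in a pipeline.

    Parameters
    ----------
    img : ndarray of shape (H, W, 3)
        8-bit RGB pixel intensities.

    Returns
    -------
    ndarray of shape (H, W), dtype uint8
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB array, got shape {img.shape!r}"
        )
    rgb = img.astype(np.float64)
    luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)


def as_gray(img: np.ndarray) -> np.ndarray:
    """Return ``img`` as an (H, W) uint8 grayscale array.

    Accepts either a grayscale image (passed through, after a range check)
    or an (H, W, 3) RGB image (converted with :func:`rgb_to_gray`).
    """
    img = np.asarray(img)
    if img.ndim == 3:
        return rgb_to_gray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D or (H, W, 3) array, got shape {img.shape!r}")
    if img.size == 0:
        raise ValueError("empty image")
    if img.dtype != np.uint8:
        arr = np.asarray(img)
        if np.issubdtype(arr.dtype, np.floating) or arr.min() < 0 or arr.max() > 255:
            raise ValueError("grayscale image must hold integers in [0, 255]")
        img = arr.astype(np.uint8)
    return img
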