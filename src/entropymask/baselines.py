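"""Baseline tissue maskers: Otsu, adaptive thresholding, and a blur+fuzz masker.

All baselines share the entropy masker's contract — an (H, W) boolean mask
with foreground = tissue — and the brightfield polarity convention: tissue
is darker than the near-white slide background, so intensity thresholds
select the *dark* side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import as_gray

__all__ = [
    "otsu_threshold",
    "otsu_mask",
    "AdaptiveParams",
    "adaptive_mask",
    "SlideMaskParams",
    "slidemask_like",
]


def otsu_threshold(gray: np.ndarray) -> int | None:
    """Otsu's global threshold on the 256-bin intensity histogram.

    Returns the intensity t* minimizing the weighted intra-class variance
    of the split {values <= t*} / {values > t*}, with ties going to the
    lowest t.  Returns ``None`` for a constant image, where no split leaves
    both classes nonempty.
    """
    gray = as_gray(gray)
    counts = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    values = np.arange(256, dtype=np.float64)

    total = counts.sum()
    w = np.cumsum(counts)
    m = np.cumsum(counts * values)
    q = np.cumsum(counts * values * values)
    w0, w1 = w[:-1], total - w[:-1]
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (m[-1] - m[:-1]) / w1
        var0 = q[:-1] / w0 - mu0 * mu0
        var1 = (q[-1] - q[:-1]) / w1 - mu1 * mu1
        within = (w0 / total) * var0 + (w1 / total) * var1
    within = np.where(valid, within, np.inf)
    return int(np.argmin(within))


def otsu_mask(gray: np.ndarray) -> np.ndarray:
    """Binary tissue mask from Otsu's threshold: foreground = values <= t*.

    A constant image has no valid two-class split and maps entirely to
    background.
    """
    gray = as_gray(gray)
    t = otsu_threshold(gray)
    if t is None:
        return np.zeros(gray.shape, dtype=bool)
    return gray <= t


@dataclass(frozen=True)
class AdaptiveParams:
    """Adaptive-threshold settings.

    block_size : odd neighborhood side length (>= 3)
    offset_c : constant subtracted from the local statistic
    mode : "mean" (plain neighborhood mean) or "gaussian" (Gaussian-weighted
        mean; the kernel sigma follows the usual size-derived convention
        ``0.3 * ((block_size - 1) / 2 - 1) + 0.8``)
    """

    block_size: int = 11
    offset_c: float = 2.0
    mode: str = "mean"

    def __post_init__(self):
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError(
                f"block_size must be odd and >= 3, got {self.block_size}"
            )
        if self.mode not in ("mean", "gaussian"):
            raise ValueError(f"mode must be 'mean' or 'gaussian', got {self.mode!r}")


def _gaussian_kernel_1d(size: int) -> np.ndarray:
    sigma = 0.3 * ((size - 1) * 0.5 - 1) + 0.8
    x = np.arange(size, dtype=np.float64) - (size - 1) / 2
    k = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return k / k.sum()


def adaptive_mask(gray: np.ndarray, params: AdaptiveParams | None = None, **kwargs) -> np.ndarray:
    """Per-pixel adaptive thresholding (dark-tissue polarity).

    The local threshold at each pixel is the neighborhood mean (or
    Gaussian-weighted mean) over a ``block_size``-square window minus
    ``offset_c``; a pixel is foreground iff its value is strictly below its
    local threshold.  The border uses mirror padding.
    """
    if params is None:
        params = AdaptiveParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword settings, not both")
    gray = as_gray(gray)
    g = gray.astype(np.float64)
    if params.mode == "mean":
        local = ndimage.uniform_filter(g, size=params.block_size, mode="reflect")
    else:
        k = _gaussian_kernel_1d(params.block_size)
        local = ndimage.correlate1d(g, k, axis=0, mode="reflect")
        local = ndimage.correlate1d(local, k, axis=1, mode="reflect")
    return g < local - params.offset_c


@dataclass(frozen=True)
class SlideMaskParams:
    """Blur+fuzz masker settings.

    blur_sigma : Gaussian blur width in pixels (suppresses dust/speckle)
    fuzz : color-distance tolerance as a fraction of the maximum possible
        RMS distance between two 8-bit RGB colors (255)
    """

    blur_sigma: float = 2.0
    fuzz: float = 0.1

    def __post_init__(self):
        if self.blur_sigma <= 0:
            raise ValueError(f"blur_sigma must be > 0, got {self.blur_sigma}")
        if not 0.0 <= self.fuzz <= 1.0:
            raise ValueError(f"fuzz must lie in [0, 1], got {self.fuzz}")


def slidemask_like(img: np.ndarray, params: SlideMaskParams | None = None, **kwargs) -> np.ndarray:
    """Blur-then-fuzz background subtraction in RGB space.

    Approximates the classic shell-tool recipe: (1) Gaussian-blur the RGB
    image to wash out dust and speckles; (2) estimate the background color
    as the modal color of the four 16x16 corner patches of the blurred
    image; (3) mark as background every pixel whose root-mean-squared
    per-channel distance from that color is within ``fuzz * 255``; tissue
    is the complement.  This is a reimplementation of the idea, not a
    bit-exact clone of any particular tool.
    """
    if params is None:
        params = SlideMaskParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword settings, not both")
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {img.shape!r}")

    blurred = ndimage.gaussian_filter(
        img.astype(np.float64), sigma=(params.blur_sigma, params.blur_sigma, 0),
        mode="reflect",
    )
    blurred_u8 = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)

    h, w = img.shape[:2]
    ph, pw = min(16, h), min(16, w)
    corners = np.concatenate(
        [
            blurred_u8[:ph, :pw].reshape(-1, 3),
            blurred_u8[:ph, w - pw :].reshape(-1, 3),
            blurred_u8[h - ph :, :pw].reshape(-1, 3),
            blurred_u8[h - ph :, w - pw :].reshape(-1, 3),
        ]
    )
    colors, counts = np.unique(corners, axis=0, return_counts=True)
    background_color = colors[int(np.argmax(counts))].astype(np.float64)

    diff = blurred - background_color
    rms = np.sqrt(np.mean(diff * diff, axis=-1))
    return rms > params.fuzz * 255.0
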