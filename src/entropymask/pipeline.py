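"""Method dispatch and the multi-method benchmark driver."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .baselines import (
    AdaptiveParams,
    SlideMaskParams,
    adaptive_mask,
    otsu_mask,
    slidemask_like,
)
from .entropy import entropy_mask
from .image import as_gray
from .metrics import CANONICAL_METHOD_ORDER, MaskMetrics, evaluate_mask, summarize_benchmark

__all__ = ["METHODS", "mask_image", "benchmark_masks", "run_benchmark"]

#: Names accepted by :func:`mask_image`, in canonical report order.
METHODS = CANONICAL_METHOD_ORDER


def mask_image(
    img: np.ndarray,
    method: str = "entropy",
    *,
    radius: int = 5,
    n_bins: int = 256,
    smooth_window: int = 5,
    block_size: int = 11,
    offset_c: float = 2.0,
    blur_sigma: float = 2.0,
    fuzz: float = 0.1,
) -> np.ndarray:
    """Compute a tissue mask with the named method.

    ``img`` is an (H, W, 3) RGB or (H, W) grayscale 8-bit array; methods
    that operate on grayscale convert internally.  Unused parameters are
    ignored, so one call signature serves every method.
    """
    if method == "entropy":
        return entropy_mask(img, radius=radius, n_bins=n_bins, smooth_window=smooth_window)
    if method == "otsu":
        return otsu_mask(as_gray(img))
    if method in ("adaptive_mean", "adaptive_gaussian"):
        mode = "mean" if method == "adaptive_mean" else "gaussian"
        params = AdaptiveParams(block_size=block_size, offset_c=offset_c, mode=mode)
        return adaptive_mask(as_gray(img), params)
    if method == "slidemask":
        img = np.asarray(img)
        if img.ndim != 3:
            img = np.stack([img] * 3, axis=-1)
        return slidemask_like(img, SlideMaskParams(blur_sigma=blur_sigma, fuzz=fuzz))
    raise ValueError(f"unknown method {method!r}; available: {list(METHODS)}")


def benchmark_masks(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]],
    methods: Sequence[str] = METHODS,
    **mask_kwargs,
) -> tuple[pd.DataFrame, list[tuple[str, MaskMetrics]]]:
    """Run several maskers over (image, truth) pairs and summarize.

    Returns the per-method mean ± SD summary table and the raw per-image
    (method, metrics) records behind it.
    """
    records: list[tuple[str, MaskMetrics]] = []
    for img, truth in pairs:
        for method in methods:
            pred = mask_image(img, method, **mask_kwargs)
            records.append((method, evaluate_mask(pred, truth)))
    return summarize_benchmark(records), records


def run_benchmark(slides, methods: Sequence[str] = METHODS, **mask_kwargs):
    """Benchmark over :class:`~entropymask.synth.SyntheticSlide` objects."""
    return benchmark_masks(
        ((s.image, s.truth) for s in slides), methods=methods, **mask_kwargs
    )
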