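"""Local-entropy tissue masking.

Brightfield slide background is bright and texturally flat, while tissue —
even faintly stained, porous tissue — carries fine intensity texture.  The
Shannon entropy of the grayscale distribution inside a small disk around
each pixel is therefore low on background and high on tissue regardless of
absolute stain intensity, which is what defeats plain intensity thresholds
on weakly immunostained or translucent sections.

The pipeline implemented here:

1. convert the RGB slide to grayscale;
2. compute the local entropy map over a disk footprint (default radius 5);
3. histogram all local entropies — background and tissue form two modes;
4. place the threshold at the valley (local minimum) between the two modes;
5. binarize: pixels with entropy strictly above the threshold are tissue.

Every step is deterministic; identical inputs give bit-identical masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .image import as_gray

__all__ = [
    "disk_footprint",
    "local_entropy_map",
    "EntropyHistogram",
    "build_entropy_histogram",
    "ThresholdDecision",
    "select_entropy_threshold",
    "binarize",
    "EntropyMaskResult",
    "entropy_mask",
]


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk of shape ``(2r+1, 2r+1)``: offsets with dy² + dx² ≤ r².

    The footprint is symmetric under negation and always contains the
    center; for radius 5 it covers 81 pixels.
    """
    radius = int(radius)
    if radius < 1:
        raise ValueError(f"footprint radius must be >= 1, got {radius}")
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (dy * dy + dx * dx) <= radius * radius


def _entropy_of_sorted_runs(win: np.ndarray) -> np.ndarray:
    """Entropy in bits of the value multiset along the last axis of ``win``.

    ``win`` has shape (..., K).  Sorting each neighborhood groups equal gray
    values into runs; the run lengths are the histogram counts, so the
    entropy is -sum (len/K) log2 (len/K) over runs.  This avoids building a
    256-bin histogram per pixel and vectorizes over all pixels at once.
    """
    k = win.shape[-1]
    s = np.sort(win, axis=-1)
    starts = np.empty(s.shape, dtype=bool)
    starts[..., 0] = True
    np.not_equal(s[..., 1:], s[..., :-1], out=starts[..., 1:])

    # position of each run start, sentinel K elsewhere; the length of the
    # run starting at j is (next run start after j) - j
    idx = np.arange(k)
    pos = np.where(starts, idx, k)
    suffix_min = np.minimum.accumulate(pos[..., ::-1], axis=-1)[..., ::-1]
    nxt = np.empty_like(pos)
    nxt[..., :-1] = suffix_min[..., 1:]
    nxt[..., -1] = k

    p = np.where(starts, (nxt - idx) / k, 1.0)  # p=1 contributes 0
    return -np.sum(p * np.log2(p), axis=-1)


def local_entropy_map(
    gray: np.ndarray,
    footprint: np.ndarray | int = 5,
    *,
    row_chunk: int = 64,
) -> np.ndarray:
    """Local Shannon entropy H(F) = -Σ_i p_F(i) log2 p_F(i), in bits.

    For every pixel, ``p_F(i)`` is the relative frequency of gray value
    ``i`` among the pixels covered by the footprint centered there, with
    ``0 log2 0 := 0``.  The image border is handled by mirror (symmetric)
    padding, so edge pixels see a reflected copy of the image rather than
    an artificial dark frame.

    Parameters
    ----------
    gray : (H, W) uint8 array
        Grayscale image.
    footprint : bool array or int
        Neighborhood shape, or a disk radius (default 5).
    row_chunk : int
        Rows processed per block; bounds peak memory, does not change the
        result.

    Returns
    -------
    (H, W) float64 array
        Entropy in bits; bounded by ``log2(footprint size)``.
    """
    gray = as_gray(gray)
    if np.isscalar(footprint) or np.asarray(footprint).ndim == 0:
        footprint = disk_footprint(int(footprint))
    footprint = np.asarray(footprint, dtype=bool)
    if footprint.ndim != 2 or footprint.shape[0] % 2 == 0 or footprint.shape[1] % 2 == 0:
        raise ValueError("footprint must be a 2-D array with odd side lengths")
    if not footprint.any():
        raise ValueError("footprint is empty")

    ry, rx = footprint.shape[0] // 2, footprint.shape[1] // 2
    padded = np.pad(gray, ((ry, ry), (rx, rx)), mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(padded, footprint.shape)

    h, w = gray.shape
    out = np.empty((h, w), dtype=np.float64)
    for lo in range(0, h, row_chunk):
        hi = min(lo + row_chunk, h)
        block = windows[lo:hi][..., footprint]  # (rows, W, K) copy
        out[lo:hi] = _entropy_of_sorted_runs(block)
    return out


@dataclass(frozen=True)
class EntropyHistogram:
    """Histogram of an entropy map over equal-width bins spanning [0, max].

    ``smoothed_counts`` is a centered moving average of ``counts``; near the
    edges the window shrinks symmetrically so the average stays centered.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed_counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def _centered_moving_average(counts: np.ndarray, window: int) -> np.ndarray:
    if window % 2 != 1 or window < 1:
        raise ValueError(f"smooth_window must be odd and >= 1, got {window}")
    half = window // 2
    n = len(counts)
    csum = np.concatenate([[0.0], np.cumsum(counts, dtype=np.float64)])
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        h = min(half, i, n - 1 - i)  # shrink symmetrically at the edges
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def build_entropy_histogram(
    emap: np.ndarray, n_bins: int = 256, smooth_window: int = 5
) -> EntropyHistogram:
    """Histogram of all local entropies, plus a smoothed copy.

    Bins are equal-width over ``[0, max(emap)]``; a degenerate all-zero map
    is binned over ``[0, 1]`` so the histogram is still well formed.
    """
    emap = np.asarray(emap, dtype=np.float64)
    if emap.size == 0:
        raise ValueError("empty entropy map")
    if int(n_bins) < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    vmax = float(emap.max())
    if vmax <= 0.0:
        vmax = 1.0
    counts, edges = np.histogram(emap, bins=int(n_bins), range=(0.0, vmax))
    smoothed = _centered_moving_average(counts.astype(np.float64), int(smooth_window))
    return EntropyHistogram(bin_edges=edges, counts=counts, smoothed_counts=smoothed)


@dataclass(frozen=True)
class ThresholdDecision:
    """Chosen entropy threshold and how it was chosen.

    ``method`` is ``"valley_minimum"`` when a valley between the two
    dominant histogram modes exists, otherwise
    ``"fallback_otsu_on_entropy"`` (unimodal or degenerate histograms).
    """

    threshold: float
    method: str
    valley_bin_index: int | None = None


def _runs(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of equal values as (start, end_exclusive, value)."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i, float(values[start])))
            start = i
    return runs


def _otsu_split_index(counts: np.ndarray, values: np.ndarray) -> int:
    """Otsu's criterion on a 1-D histogram: the split index t (class 0 =
    bins <= t) minimizing the weighted intra-class variance.  Ties take the
    lowest t; a histogram with all mass in one bin returns that bin."""
    counts = np.asarray(counts, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram has zero total count")

    w = np.cumsum(counts)
    m = np.cumsum(counts * values)
    q = np.cumsum(counts * values * values)
    w0, w1 = w[:-1], total - w[:-1]
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return int(np.argmax(counts))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (m[-1] - m[:-1]) / w1
        var0 = q[:-1] / w0 - mu0 * mu0
        var1 = (q[-1] - q[:-1]) / w1 - mu1 * mu1
        within = (w0 / total) * var0 + (w1 / total) * var1
    within = np.where(valid, within, np.inf)
    return int(np.argmin(within))


def select_entropy_threshold(hist: EntropyHistogram) -> ThresholdDecision:
    """Pick the threshold at the valley of the (smoothed) entropy histogram.

    The smoothed histogram of a slide with both tissue and background is
    bimodal: a low-entropy background mode and a high-entropy tissue mode.
    Local minima are bins strictly lower than both neighbors, with plateaus
    collapsed to their leftmost bin.  Among the minima lying strictly
    between the two highest local maxima, the deepest one wins (ties go to
    the lowest bin); the threshold is that bin's center.  When no such
    valley exists (unimodal or degenerate histogram — e.g. an empty slide),
    Otsu's criterion applied to the entropy histogram is used instead and
    the decision is tagged accordingly.
    """
    counts = np.asarray(hist.counts)
    if counts.sum() <= 0:
        raise ValueError("histogram has zero total count")
    smoothed = np.asarray(hist.smoothed_counts, dtype=np.float64)
    centers = hist.bin_centers

    runs = _runs(smoothed)
    maxima = []  # (value, run_start, run_end)
    minima = []
    for j, (start, end, value) in enumerate(runs):
        left = runs[j - 1][2] if j > 0 else None
        right = runs[j + 1][2] if j + 1 < len(runs) else None
        higher_than_left = left is None or value > left
        higher_than_right = right is None or value > right
        if higher_than_left and higher_than_right:
            maxima.append((value, start, end))
        if left is not None and right is not None and value < left and value < right:
            minima.append((value, start, end))

    if len(maxima) >= 2 and minima:
        # two dominant modes: highest smoothed count wins, ties to the left
        top_two = sorted(maxima, key=lambda m: (-m[0], m[1]))[:2]
        top_two.sort(key=lambda m: m[1])
        (_, _, a_end), (_, b_start, _) = top_two
        candidates = [
            (value, start)
            for value, start, end in minima
            if start >= a_end and end <= b_start
        ]
        if candidates:
            value, bin_index = min(candidates)
            return ThresholdDecision(
                threshold=float(centers[bin_index]),
                method="valley_minimum",
                valley_bin_index=int(bin_index),
            )

    t = _otsu_split_index(counts, centers)
    return ThresholdDecision(
        threshold=float(centers[t]),
        method="fallback_otsu_on_entropy",
        valley_bin_index=None,
    )


def binarize(emap: np.ndarray, threshold: float) -> np.ndarray:
    """Entropy map -> boolean tissue mask: foreground iff entropy > threshold.

    The inequality is strict, so pixels exactly at the threshold are
    background — a deterministic tie rule.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return np.asarray(emap) > threshold


class EntropyMaskResult(NamedTuple):
    mask: np.ndarray
    entropy_map: np.ndarray
    histogram: EntropyHistogram
    decision: ThresholdDecision


def entropy_mask(
    img: np.ndarray,
    radius: int = 5,
    n_bins: int = 256,
    smooth_window: int = 5,
    *,
    return_details: bool = False,
) -> np.ndarray | EntropyMaskResult:
    """Run the full local-entropy masking pipeline on a slide image.

    Parameters
    ----------
    img : (H, W, 3) RGB or (H, W) grayscale 8-bit array
    radius : int
        Disk footprint radius in pixels (default 5).
    n_bins, smooth_window : int
        Entropy-histogram resolution and smoothing window.
    return_details : bool
        If true, also return the entropy map, histogram and threshold
        decision for inspection.

    Returns
    -------
    boolean (H, W) tissue mask, or an :class:`EntropyMaskResult`.
    """
    gray = as_gray(img)
    emap = local_entropy_map(gray, disk_footprint(radius))
    hist = build_entropy_histogram(emap, n_bins=n_bins, smooth_window=smooth_window)
    decision = select_entropy_threshold(hist)
    mask = binarize(emap, decision.threshold)
    if return_details:
        return EntropyMaskResult(mask, emap, hist, decision)
    return mask
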