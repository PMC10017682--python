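"""Shared fixtures and independent brute-force oracles.

The oracles here recompute quantities by direct enumeration, independently
of the library's vectorized code paths, so tests compare two routes to the
same number.
"""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def entropy_oracle(gray: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel local entropy by explicit neighborhood enumeration.

    Mirrors the definition directly: mirror-pad, gather the footprint
    pixels one center at a time, histogram them, and evaluate
    -sum p log2 p.  Deliberately loop-based and independent of the
    vectorized implementation.
    """
    gray = np.asarray(gray, dtype=np.uint8)
    h, w = gray.shape
    padded = np.pad(gray, radius, mode="symmetric")
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    inside = (dy * dy + dx * dx) <= radius * radius
    offs = np.argwhere(inside) - radius
    out = np.empty((h, w), dtype=np.float64)
    for y in range(h):
        for x in range(w):
            vals = padded[y + radius + offs[:, 0], x + radius + offs[:, 1]]
            counts = np.bincount(vals)
            p = counts[counts > 0] / len(vals)
            out[y, x] = float(-(p * np.log2(p)).sum())
    return out


def otsu_oracle(counts: np.ndarray) -> int | None:
    """Exhaustive Otsu search in exact rational arithmetic.

    Tries every split t of a histogram with integer counts and returns the
    t minimizing the weighted intra-class variance, evaluated with
    :class:`fractions.Fraction` so exact ties (e.g. splits separated only
    by empty bins) are resolved deterministically to the lowest t rather
    than by floating-point roundoff.  None if no split leaves both classes
    nonempty.
    """
    from fractions import Fraction

    counts = [int(c) for c in np.asarray(counts)]
    total = sum(counts)
    total_m = sum(c * v for v, c in enumerate(counts))
    total_q = sum(c * v * v for v, c in enumerate(counts))
    best_t, best_var = None, None
    w0 = m0 = q0 = 0
    for t in range(len(counts) - 1):
        w0 += counts[t]
        m0 += counts[t] * t
        q0 += counts[t] * t * t
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m1, q1 = total_m - m0, total_q - q0
        var0 = Fraction(q0, w0) - Fraction(m0, w0) ** 2
        var1 = Fraction(q1, w1) - Fraction(m1, w1) ** 2
        within = Fraction(w0, total) * var0 + Fraction(w1, total) * var1
        if best_var is None or within < best_var:
            best_var, best_t = within, t
    return best_t
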