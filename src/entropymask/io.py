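"""Raster I/O: slide loading (incl. multi-page TIFF pyramids), mask files,
entropy-map export and pseudocolor overlays.

Whole-slide files are commonly stored as multi-resolution (pyramidal)
TIFFs; masking runs on a coarse level, so :func:`read_image` exposes an
explicit ``level`` plus an ``auto`` rule — the largest (finest) level whose
maximum dimension fits within ``max_dim``.  Vendor formats (.ndpi etc.) are
out of scope; convert to TIFF/PNG first.

Masks are written as single-channel 8-bit PNG with 255 = tissue and
0 = background, and validate as strictly two-valued on read-back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger("entropymask")

__all__ = [
    "MaskingIOError",
    "MissingFileError",
    "ImageFormatError",
    "LevelOutOfRangeError",
    "LoadSpec",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "write_entropy_map",
    "overlay_mask",
]


class MaskingIOError(Exception):
    """Base class for slide/mask I/O failures."""


class MissingFileError(MaskingIOError):
    """Input file does not exist."""


class ImageFormatError(MaskingIOError):
    """File exists but cannot be decoded as a supported raster."""


class LevelOutOfRangeError(MaskingIOError):
    """Requested pyramid level does not exist in the file."""


@dataclass(frozen=True)
class LoadSpec:
    """How to load a slide: path, pyramid level (or "auto"), size cap.

    In ``auto`` mode the largest level whose maximum dimension is at most
    ``max_dim`` is chosen; if every level is bigger, the coarsest one is
    used with a warning.
    """

    path: str | Path
    level: int | str = "auto"
    max_dim: int = 5000

    def __post_init__(self):
        if isinstance(self.level, str):
            if self.level != "auto":
                raise ValueError(f"level must be an integer or 'auto', got {self.level!r}")
        elif self.level < 0:
            raise ValueError(f"level must be >= 0, got {self.level}")
        if self.max_dim < 64:
            raise ValueError(f"max_dim must be >= 64, got {self.max_dim}")


def _to_uint8_rgb(arr: np.ndarray, source: str) -> np.ndarray:
    if arr.dtype == np.uint16:
        arr = (arr >> 8).astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        raise ImageFormatError(f"{source}: unsupported pixel dtype {arr.dtype}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[-1] != 3:
        raise ImageFormatError(f"{source}: unsupported image shape {arr.shape!r}")
    return np.ascontiguousarray(arr)


def read_image(
    spec: LoadSpec | str | Path,
    level: int | str = "auto",
    max_dim: int = 5000,
) -> np.ndarray:
    """Load a slide image as (H, W, 3) uint8 RGB.

    PNG/JPEG are single-level; TIFFs may carry several pages, treated as
    pyramid levels in file order (finest first, as is conventional).
    Grayscale sources are replicated to three channels.
    """
    if not isinstance(spec, LoadSpec):
        spec = LoadSpec(path=spec, level=level, max_dim=max_dim)
    path = Path(spec.path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")

    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tif:
                shapes = [p.shape[:2] for p in tif.pages]
                if spec.level == "auto":
                    fitting = [
                        i for i, (h, w) in enumerate(shapes)
                        if max(h, w) <= spec.max_dim
                    ]
                    if fitting:
                        idx = max(fitting, key=lambda i: shapes[i][0] * shapes[i][1])
                    else:
                        idx = min(
                            range(len(shapes)), key=lambda i: shapes[i][0] * shapes[i][1]
                        )
                        logger.warning(
                            "%s: no level fits max_dim=%d; using coarsest level %d %r",
                            path, spec.max_dim, idx, shapes[idx],
                        )
                else:
                    idx = int(spec.level)
                    if idx >= len(shapes):
                        raise LevelOutOfRangeError(
                            f"{path}: level {idx} out of range (file has "
                            f"{len(shapes)} levels)"
                        )
                arr = tif.pages[idx].asarray()
        except LevelOutOfRangeError:
            raise
        except tifffile.TiffFileError as exc:
            raise ImageFormatError(f"{path}: not a readable TIFF ({exc})") from exc
        logger.info("loaded %s level %d, shape %r", path, idx, arr.shape[:2])
        return _to_uint8_rgb(arr, str(path))

    if spec.level not in ("auto", 0):
        raise LevelOutOfRangeError(
            f"{path}: single-level format, level {spec.level} out of range"
        )
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"{path}: undecodable image ({exc})") from exc
    logger.info("loaded %s, shape %r", path, arr.shape[:2])
    return np.ascontiguousarray(arr)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) uint8 RGB image as PNG/JPEG/TIFF by suffix."""
    img = np.asarray(img)
    if img.dtype != np.uint8 or img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) uint8 image")
    Image.fromarray(img, mode="RGB").save(path)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean tissue mask as 8-bit PNG, 255 = tissue, 0 = background."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape!r}")
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.isin(vals, (0, 1, 255)).all():
            raise ValueError("mask must be strictly two-valued")
        mask = mask > 0
    Image.fromarray(mask.astype(np.uint8) * 255, mode="L").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 (or 0/1) single-channel mask PNG back as boolean."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 255)).all():
        raise ImageFormatError(
            f"{path}: not a binary mask (values {vals[:10].tolist()} ...)"
        )
    return arr > 0


def write_entropy_map(emap: np.ndarray, path: str | Path) -> None:
    """Write an entropy map as a 32-bit float single-channel TIFF."""
    emap = np.asarray(emap, dtype=np.float32)
    if emap.ndim != 2:
        raise ValueError(f"entropy map must be 2-D, got shape {emap.shape!r}")
    tifffile.imwrite(path, emap)


def overlay_mask(
    img: np.ndarray,
    mask: np.ndarray,
    color: tuple[int, int, int] = (0, 255, 0),
    alpha: float = 0.5,
) -> np.ndarray:
    """Alpha-blend mask foreground toward a pseudocolor; background unchanged."""
    img = np.asarray(img)
    mask = np.asarray(mask).astype(bool)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape!r}")
    if img.shape[:2] != mask.shape:
        raise ValueError(
            f"image/mask shape mismatch: {img.shape[:2]!r} vs {mask.shape!r}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    out = img.astype(np.float64)
    out[mask] = (1.0 - alpha) * out[mask] + alpha * np.asarray(color, dtype=np.float64)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
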