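"""Synthetic brightfield slide generator with exact ground-truth masks.

Real whole-slide images defeat naive intensity thresholds in specific,
well-understood ways: porous tissue full of background-colored voids
(collagen gaps, decalcification), faint or translucent (immuno)staining
whose mean intensity barely departs from the background, background color
drift across the slide, seam lines from tile-based scanning, and dust.
This module renders small slides that exhibit exactly those failure modes
while recording the tissue ground truth pixel-for-pixel, so maskers can be
benchmarked without manual annotation.

A slide is built deterministically from a :class:`SlideRecipe` whose seed
drives a ``numpy.random.Generator`` (PCG64); the same recipe always yields
a bit-identical image and truth mask.

Rendering model
---------------
* Background: a near-white base level (245 ± 5, drawn once per slide) plus
  a linear per-channel tint gradient (blue→yellow drift) and per-pixel
  sensor noise.
* Tissue: a union of smooth random blobs (ellipses warped by a low-order
  Fourier perturbation of the boundary radius), colored by blending the
  background toward a stain color.  The blend weight is
  ``stain_strength ** 2``: chromogen deposition responds superlinearly to
  stain strength, so weakly stained tissue is disproportionately close to
  background color — the translucent-tissue failure mode.  A shared
  Gaussian texture field (the optical texture of real tissue) is added to
  all three channels inside tissue; this texture, not the stain contrast,
  is what local-entropy masking keys on.
* Porosity: circular holes are punched out of the tissue until the
  requested fraction of blob area is background-colored; punched pixels
  are removed from the truth mask.
* Artifacts: 1-px darker seam lines on a tile grid, and small dark dust
  specks stamped on the background.  Dust is *not* tissue and stays out of
  the truth mask.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SlideRecipe",
    "SyntheticSlide",
    "generate_slide",
    "generate_benchmark_set",
    "PRESETS",
    "preset_recipe",
    "preset_recipes",
    "recipes_from_manifest",
]


@dataclass(frozen=True)
class SlideRecipe:
    """Parameter set fully describing one synthetic slide.

    Attributes
    ----------
    height, width : image size in pixels (>= 64)
    n_blobs : number of tissue blobs
    blob_scale : characteristic blob diameter as a fraction of min(H, W)
    porosity : fraction of tissue area punched out as background-colored
        holes (in [0, 1])
    hole_radius : maximum hole radius in pixels (hole radii are drawn
        uniformly between 0.4 and 1.0 times this)
    stain_strength : stain intensity in [0, 1]; 0 leaves tissue nearly
        background-colored, 1 is a fully saturated stain
    stain_rgb : fully-stained tissue color (default a desaturated
        eosin-like pink)
    texture_sigma : SD of the shared per-pixel texture noise inside tissue
    bg_noise_sigma : SD of the per-pixel background sensor noise
    bg_tint_gradient : maximum per-channel drift across the image (models
        color-temperature drift from blue-ish to yellow-ish)
    tile_size, seam_strength : spacing (px) and darkening (intensity) of
        scanner tile-seam lines; tile_size 0 disables seams
    n_dust, dust_radius : number and maximum radius of dark dust specks
        stamped on the background
    seed : seed of the slide's random generator
    """

    height: int = 512
    width: int = 512
    n_blobs: int = 3
    blob_scale: float = 0.30
    porosity: float = 0.0
    hole_radius: int = 16
    stain_strength: float = 0.85
    stain_rgb: tuple[int, int, int] = (180, 85, 130)
    texture_sigma: float = 8.0
    bg_noise_sigma: float = 2.0
    bg_tint_gradient: float = 5.0
    tile_size: int = 0
    seam_strength: float = 0.0
    n_dust: int = 0
    dust_radius: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.height < 64 or self.width < 64:
            raise ValueError("slide dimensions must be >= 64")
        for name in ("porosity", "stain_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")
        if not 0.0 < self.blob_scale <= 1.0:
            raise ValueError("blob_scale must lie in (0, 1]")
        if self.hole_radius < 1 or self.dust_radius < 1:
            raise ValueError("hole_radius and dust_radius must be >= 1")
        for name in ("texture_sigma", "bg_noise_sigma", "bg_tint_gradient",
                     "seam_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tile_size < 0 or self.n_dust < 0:
            raise ValueError("tile_size and n_dust must be >= 0")


@dataclass(frozen=True)
class SyntheticSlide:
    """A rendered slide, its exact truth mask, and the recipe that made it."""

    image: np.ndarray  # (H, W, 3) uint8
    truth: np.ndarray  # (H, W) bool, True = tissue
    recipe: SlideRecipe


def _disk_indices(cy: float, cx: float, r: float, h: int, w: int):
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return (slice(y0, y1), slice(x0, x1)), inside


def _random_blob(rng: np.random.Generator, h: int, w: int, scale: float) -> np.ndarray:
    """One smooth blob: an ellipse-ish region with a Fourier-warped boundary."""
    cy = rng.uniform(0.30, 0.70) * h
    cx = rng.uniform(0.30, 0.70) * w
    r0 = 0.5 * scale * min(h, w) * rng.uniform(0.75, 1.25)
    ks = np.arange(2, 7)
    amps = rng.normal(0.0, 0.35 / ks)
    phases = rng.uniform(0.0, 2 * np.pi, size=ks.size)

    rmax = r0 * (1.0 + np.abs(amps).sum())
    y0, y1 = max(0, int(cy - rmax) - 1), min(h, int(cy + rmax) + 2)
    x0, x1 = max(0, int(cx - rmax) - 1), min(w, int(cx + rmax) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = r0 * np.maximum(
        0.3, 1.0 + np.sum(amps[:, None, None]
                          * np.cos(ks[:, None, None] * theta + phases[:, None, None]),
                          axis=0)
    )
    blob = np.zeros((h, w), dtype=bool)
    blob[y0:y1, x0:x1] = dist <= boundary
    return blob


def _punch_holes(
    rng: np.random.Generator, tissue: np.ndarray, porosity: float, hole_radius: int
) -> np.ndarray:
    """Punch circular holes until ~porosity of the tissue area is removed.

    Returns the hole mask.  Hole centers are drawn uniformly over tissue
    pixels; punching stops at the first crossing of the target area, so the
    realized porosity overshoots by at most one hole.
    """
    holes = np.zeros_like(tissue)
    if porosity <= 0:
        return holes
    h, w = tissue.shape
    tissue_idx = np.flatnonzero(tissue)
    target = porosity * tissue_idx.size
    punched = 0
    for _ in range(100_000):
        if punched >= target:
            break
        flat = tissue_idx[rng.integers(tissue_idx.size)]
        cy, cx = divmod(int(flat), w)
        r = hole_radius * rng.uniform(0.4, 1.0)
        sl, inside = _disk_indices(cy, cx, r, h, w)
        fresh = inside & tissue[sl] & ~holes[sl]
        punched += int(fresh.sum())
        holes[sl] |= fresh
    return holes


def generate_slide(recipe: SlideRecipe) -> SyntheticSlide:
    """Render one synthetic slide deterministically from its recipe."""
    rng = np.random.default_rng(recipe.seed)
    h, w = recipe.height, recipe.width

    # -- background field: base level, tint gradient, sensor noise
    base = 245.0 + rng.uniform(-5.0, 5.0)
    angle = rng.uniform(0.0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    proj = (np.cos(angle) * (xx / max(w - 1, 1) - 0.5)
            + np.sin(angle) * (yy / max(h - 1, 1) - 0.5))
    tint = np.empty((h, w, 3), dtype=np.float64)
    g = recipe.bg_tint_gradient
    tint[..., 0] = g * proj          # warmer on one side ...
    tint[..., 1] = 0.3 * g * proj
    tint[..., 2] = -g * proj         # ... cooler on the other

    # -- tissue geometry, then porosity; truth is fixed before rendering
    tissue_full = np.zeros((h, w), dtype=bool)
    for _ in range(recipe.n_blobs):
        tissue_full |= _random_blob(rng, h, w, recipe.blob_scale)
    holes = _punch_holes(rng, tissue_full, recipe.porosity, recipe.hole_radius)
    truth = tissue_full & ~holes

    # -- render: background everywhere, stain blend + texture inside tissue
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = base
    img += tint
    img += rng.normal(0.0, recipe.bg_noise_sigma, size=(h, w, 3))

    s_eff = recipe.stain_strength ** 2
    stain = np.asarray(recipe.stain_rgb, dtype=np.float64)
    blended = img[truth] + s_eff * (stain - img[truth])
    texture = rng.normal(0.0, recipe.texture_sigma, size=int(truth.sum()))
    img[truth] = blended + texture[:, None]

    # -- tile-seam lines (1 px darker along the tile grid)
    if recipe.tile_size > 0 and recipe.seam_strength > 0:
        for x in range(recipe.tile_size, w, recipe.tile_size):
            img[:, x, :] -= recipe.seam_strength
        for y in range(recipe.tile_size, h, recipe.tile_size):
            img[y, :, :] -= recipe.seam_strength

    # -- dust specks: dark, on background only, never in truth
    for _ in range(recipe.n_dust):
        for _attempt in range(100):
            cy = int(rng.integers(h))
            cx = int(rng.integers(w))
            if not tissue_full[cy, cx]:
                break
        r = recipe.dust_radius * rng.uniform(0.5, 1.0)
        shade = rng.uniform(60.0, 110.0)
        sl, inside = _disk_indices(cy, cx, r, h, w)
        stamp = inside & ~truth[sl]
        img[sl][stamp] = shade + rng.normal(0.0, 5.0, size=(int(stamp.sum()), 1))

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticSlide(image=image, truth=truth, recipe=recipe)


#: Named study conditions.  ``easy`` is clean, well-stained tissue;
#: ``porous`` punches out a third of the tissue; ``faint`` emulates weak
#: immunostaining; ``porous_faint`` combines both (the regime where
#: intensity thresholds fail hardest); ``artifact_heavy`` adds tint drift,
#: tile seams and dust.
PRESETS: dict[str, dict] = {
    "easy": dict(blob_scale=0.35, porosity=0.0, stain_strength=0.9,
                 texture_sigma=8.0, bg_tint_gradient=4.0),
    "porous": dict(porosity=0.35, stain_strength=0.8),
    "faint": dict(porosity=0.0, stain_strength=0.3),
    "porous_faint": dict(porosity=0.4, stain_strength=0.25),
    "artifact_heavy": dict(porosity=0.2, stain_strength=0.6,
                           bg_tint_gradient=12.0, tile_size=128,
                           seam_strength=6.0, n_dust=30, dust_radius=3),
}


def preset_recipe(name: str, seed: int = 0, **overrides) -> SlideRecipe:
    """A :class:`SlideRecipe` for a named preset, with optional overrides."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    fields = dict(PRESETS[name])
    fields.update(overrides)
    return SlideRecipe(seed=seed, **fields)


def preset_recipes(name: str, n: int, start_seed: int = 0, **overrides) -> list[SlideRecipe]:
    """``n`` recipes of a preset with consecutive seeds start_seed..start_seed+n-1."""
    return [preset_recipe(name, seed=start_seed + i, **overrides) for i in range(n)]


def generate_benchmark_set(
    recipes: list[SlideRecipe], out_dir: str | Path | None = None
) -> list[SyntheticSlide]:
    """Generate one slide per recipe, optionally writing them to disk.

    When ``out_dir`` is given, writes ``slide_###.png`` (RGB image),
    ``truth_###.png`` (0/255 mask) and a ``manifest.csv`` holding every
    recipe field, so the set can be regenerated bit-identically from the
    manifest alone.
    """
    if not recipes:
        raise ValueError("need at least one recipe")
    slides = [generate_slide(r) for r in recipes]
    if out_dir is not None:
        from .io import write_image, write_mask  # local import: io pulls PIL

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        field_names = [f.name for f in dataclasses.fields(SlideRecipe)]
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "truth_filename", *field_names])
            for i, slide in enumerate(slides):
                img_name, truth_name = f"slide_{i:03d}.png", f"truth_{i:03d}.png"
                write_image(slide.image, out / img_name)
                write_mask(slide.truth, out / truth_name)
                row = [getattr(slide.recipe, f) for f in field_names]
                writer.writerow([img_name, truth_name, *row])
    return slides


def recipes_from_manifest(path: str | Path) -> list[SlideRecipe]:
    """Re-read the recipes of a generated set from its manifest.csv."""
    import ast

    recipes = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            kwargs = {}
            for f in dataclasses.fields(SlideRecipe):
                raw = row[f.name]
                kwargs[f.name] = ast.literal_eval(raw)
            recipes.append(SlideRecipe(**kwargs))
    return recipes
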