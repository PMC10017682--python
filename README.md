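# entropymask

Tissue/background segmentation ("masking") of brightfield histology slide
images by **local-entropy thresholding**, with four classical baseline
maskers, pixel-level evaluation metrics, and a synthetic-slide generator
with exact ground truth for benchmarking.

## The problem

Automated analysis of whole-slide images (WSI) starts by separating tissue
(foreground) from the slide background. Global or adaptive *intensity*
thresholds work when tissue is dark and background is uniformly white, but
fail on the slides that matter most in practice: porous tissue riddled with
background-colored voids (collagen gaps, decalcification), faint or
translucent (immuno)staining whose mean intensity is within a few gray
levels of the background, background color-temperature drift, tile-seam
artifacts from the scanner, and dust.

The idea here is that tissue differs from background in *texture*, not just
intensity. For each pixel, compute the Shannon entropy of the grayscale
distribution inside a disk-shaped footprint *F* of radius 5:

    H(F) = − Σ_{i=0..255} p_F(i) · log2 p_F(i),      0·log2 0 := 0

where `p_F(i)` is the relative frequency of gray level *i* among the pixels
the footprint covers. Flat background gives low entropy regardless of its
absolute brightness or tint; textured tissue gives high entropy regardless
of how faint its stain is. The histogram of all local entropies is
therefore bimodal, and the threshold is placed at the **valley (local
minimum) between the background and tissue modes**; pixels with entropy
strictly above the threshold are tissue. A degenerate slide with a
unimodal entropy histogram (e.g. no tissue at all) falls back to Otsu's
criterion applied to the entropy histogram.

Baselines implemented behind the same mask contract: Otsu's global
threshold, adaptive-mean and adaptive-Gaussian local thresholds, and a
blur+fuzz background-color subtraction (`slidemask_like`). Evaluation uses
the Jaccard index, sensitivity, false positive rate and pixel accuracy
against ground-truth masks, aggregated per method as mean ± SD.

## Worked example

```sh
python examples/mask_one_slide.py
```

builds a 512×512 synthetic slide in the hardest regime — 40 % of the
tissue punched out as background-colored pores, stain so faint the tissue
mean is ~8 gray levels from background — and masks it:

```
entropy range: 0 .. 5.043 bits (cap log2(81) = 6.340)
threshold: 3.359 bits, chosen by valley_minimum
foreground fraction: 0.173 (truth: 0.144)
Jaccard 0.830  sensitivity 0.996  FPR 0.0338  pixel accuracy 0.971
```

Entropy values are bounded by log2 81 ≈ 6.34 bits (81 pixels in the
radius-5 disk). The valley threshold of 3.36 bits separates the flat
background mode from the textured tissue mode; sensitivity 0.996 means
essentially all true tissue was recovered despite the faint stain.
`examples/compare_maskers.py` runs all five methods on five such slides:

```
           Method  Jaccard_mean  Sensitivity_mean  FPR_mean
          entropy        0.8035            0.9975    0.0335
             otsu        0.5539            0.5539    0.0000
    adaptive_mean        0.3016            0.4533    0.0680
adaptive_gaussian        0.2908            0.4289    0.0642
        slidemask        0.0000            0.0000    0.0000
```

The intensity-based methods miss roughly half of the faint tissue (or all
of it), while the entropy masker keeps its sensitivity — the qualitative
ordering that motivates the method.

## Command line

```sh
entropymask synth --preset porous_faint --n 5 --seed 0 --out-dir set/
entropymask mask set/slide_000.png --method entropy --out mask.png \
    --overlay overlay.png --save-entropy-map entropy.tif
entropymask benchmark --image-dir set/ --out-csv bench.csv
```

`mask` accepts PNG/JPEG/TIFF, including multi-page pyramidal TIFF
(`--level N` or `--level auto`, which picks the largest level whose maximum
dimension fits `--max-dim`, default 5000). Vendor formats such as `.ndpi`
are not parsed; convert to TIFF first. Masks are written as 8-bit PNG with
255 = tissue.

## Synthetic slides

`entropymask.synth` renders histology-like slides from a `SlideRecipe`
(blob geometry, porosity, stain strength, texture, tint gradient, seams,
dust) with the ground-truth mask recorded exactly, and is deterministic per
seed. Presets: `easy`, `porous`, `faint`, `porous_faint`,
`artifact_heavy`. See `docs/methods.md` for what the generator does and
does not emulate.

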