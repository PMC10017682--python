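# Methods

## Local-entropy masking

The masker classifies each pixel of a brightfield slide image as tissue or
background from the Shannon entropy of its grayscale neighborhood.

**Grayscale conversion.** RGB is reduced to 8-bit luma with the ITU-R
BT.601 weights (0.299 R + 0.587 G + 0.114 B), rounded to the nearest
integer. Any strictly monotonic remapping of gray levels leaves the
entropy map — and therefore the mask, given the same threshold selection —
bit-identical, because entropy depends only on value multiplicities. This
invariance is what makes the method robust to stain intensity, scanner
gamma and background tint.

**Local entropy.** For each pixel, the empirical distribution `p_F(i)` of
gray values over a disk footprint (offsets with dy² + dx² ≤ r², default
r = 5, 81 pixels) is formed and its entropy −Σ p log2 p computed, with
0·log2 0 := 0. Probabilities are relative frequencies over the footprint
pixels only (not a fixed 256-cell normalization), so values are bounded by
log2 81 ≈ 6.34 bits. Borders use mirror padding (numpy `symmetric`, the
same convention as scipy.ndimage's default `reflect`): zero padding would
manufacture a high-entropy frame at the image edge.

The implementation sorts each neighborhood's 81 values and reads the
histogram off the run lengths, vectorized over row blocks; this is exact
(tests compare every pixel against per-pixel brute-force enumeration at
1e-9 bits, and against an independent rank-filter implementation on
interior pixels) and runs in about 2 s for a 512×512 image on one core.

**Threshold selection.** All entropies are histogrammed over `n_bins`
equal-width bins spanning [0, max] (`n_bins` = 256; a degenerate all-zero
map spans [0, 1]) and smoothed with a centered moving average
(`smooth_window` = 5, shrinking symmetrically at the edges so edge bins
stay centered). On a slide containing both tissue and background the
smoothed histogram is bimodal. Local minima are bins strictly lower than
both neighbors, with plateaus collapsed to their leftmost bin; among the
minima lying strictly between the two highest local maxima, the deepest
(lowest count, ties to the lower bin) is the valley, and the threshold is
its bin center. If no such valley exists — unimodal or degenerate
histograms, e.g. an empty slide — the threshold falls back to Otsu's
criterion applied to the entropy histogram and the decision is tagged
`fallback_otsu_on_entropy`. Bin count, window, and the
deepest-between-the-two-modes rule are deliberate design choices: the
valley of interest is the one separating the background mode from the
tissue mode, and 256 bins with a 5-bin average resolve it without letting
shot noise split either mode.

**Binarization.** Foreground = entropy strictly greater than the
threshold; pixels exactly at the threshold are background. Strictness
makes the all-zero map with threshold 0 come out all-background, and gives
a deterministic tie rule. No morphological post-processing (hole filling,
small-object removal) is applied.

## Baseline maskers

All baselines use the dark-tissue polarity (brightfield tissue is darker
than the near-white background).

* **Otsu**: global threshold t* minimizing the weighted intra-class
  variance of the 256-bin intensity histogram; foreground = gray ≤ t*.
  Ties take the lowest t; the cumulative-sum evaluation is tie-stable
  because empty bins contribute exact zeros. A constant image has no valid
  split and maps to all-background.
* **Adaptive mean / Gaussian**: per-pixel threshold = local mean (or
  Gaussian-weighted mean) over a `block_size` square window minus
  `offset_c`; foreground = strictly below. Defaults block_size 11,
  offset_c 2 — the common library defaults; the Gaussian kernel sigma uses
  the conventional size-derived formula 0.3·((k−1)/2 − 1) + 0.8.
* **slidemask_like**: Gaussian-blur the RGB image (sigma 2), estimate the
  background color as the modal color of the four 16×16 corner patches,
  and mark as background every pixel whose RMS per-channel distance from
  it is ≤ fuzz·255 (fuzz 0.1). This reimplements the blur+fuzz idea
  behind the classic shell tooling; it is intentionally not a bit-exact
  clone, hence the `_like` suffix.

## Metrics

Per (predicted, truth) pair: Jaccard = TP/(TP+FP+FN), sensitivity =
TP/(TP+FN), false positive rate = FP/(FP+TN), pixel accuracy =
(TP+TN)/total. Conventions for cases a real benchmark never meets, chosen
to keep aggregation well-defined: two empty masks have Jaccard 1 (they are
identical) with a warning; sensitivity with empty truth and FPR with
all-tissue truth are NaN with a warning. Aggregation reports mean and
sample SD (n−1 denominator; 0 when n = 1) per method in a fixed canonical
order.

## Synthetic slide generator

The generator's purpose is to produce images that defeat intensity
thresholds the same way real slides do, with ground truth known exactly.
Each slide is rendered deterministically from a `SlideRecipe` seed through
a fixed draw order on a PCG64 generator (`numpy.random.default_rng`), so
fixtures are reproducible byte-for-byte from the manifest alone.

* **Background**: near-white base (245 ± 5, drawn per slide), a linear
  per-channel tint gradient in a random direction (warm on one side, cool
  on the other; amplitude `bg_tint_gradient`, default 5), and per-pixel
  sensor noise (σ = 2).
* **Tissue geometry**: a union of `n_blobs` smooth blobs — ellipses whose
  boundary radius is warped by a low-order Fourier series (harmonics 2–6,
  amplitudes ∝ 1/k) — with characteristic diameter `blob_scale`·min(H, W).
  512×512 slides with 2–3 blobs put the tissue boundary length in a
  realistic proportion to tissue area at thumbnail scale.
* **Stain rendering**: tissue pixels are blended from the local background
  toward a stain color (default a desaturated eosin-like pink) with weight
  `stain_strength²`. The quadratic response models chromogen deposition
  in weak immunostaining, where low stain produces disproportionately low
  contrast: at `stain_strength` 0.25 the tissue mean sits ~8 gray levels
  from the background — inside the overlap of the two intensity
  distributions, which is precisely the failure mode being emulated. A
  shared Gaussian texture field (σ = 8, added to all three channels)
  supplies the optical texture of real tissue; it is what the entropy
  filter detects, independently of stain contrast.
* **Porosity**: circular holes (radius uniform in 0.4–1.0 × `hole_radius`,
  default 16 px — the scale of decalcification voids at thumbnail
  resolution, and large enough that a radius-5 footprint can resolve their
  interiors) are punched at random tissue locations until the requested
  fraction of blob area is background-colored; punching stops at the first
  crossing of the target, overshooting by at most one hole (≈ 1 % of
  tissue area). Punched pixels are removed from the truth mask before any
  color is rendered.
* **Artifacts**: optional 1-px darker seam lines every `tile_size` pixels
  (tile-based scanning), and dark dust specks stamped on background only.
  Dust is contamination, not tissue, and is never truth-foreground.

**What the generator does not emulate**: real stain spectra and
stain-specific morphology (nuclei, fibers), optical blur and chromatic
aberration, annotation error in the ground truth, coverslip bubbles and
marker stripes, and pyramidal multi-resolution structure. Passing the
synthetic benchmarks therefore demonstrates that each masker behaves as
designed under the targeted failure modes — not a clinical performance
claim for any particular stain or scanner.

**Presets** (the study conditions used by the tests and the acceptance
script): `easy` (clean, well-stained), `porous` (35 % holes), `faint`
(stain 0.3), `porous_faint` (40 % holes, stain 0.25 — the hardest regime),
`artifact_heavy` (tint drift 12, seams, 30 dust specks).

## Problem sizes

Benchmarks run on 512×512 slides: 20 `porous_faint` slides for the
five-method comparison and 10 `easy` slides for the recovery check, sizes
at which the tissue-boundary fringe (a footprint-radius-wide band of
elevated entropy around true tissue) costs the entropy masker only a few
Jaccard points, as it does on real thumbnails. The whole acceptance run
completes in about a minute on one core.

## Known limitations

* The entropy masker dilates the mask by up to the footprint radius around
  true tissue and around pores smaller than the footprint — the price of
  its near-perfect sensitivity; it trades false positives for recall.
* Valley selection assumes the two dominant modes of the smoothed entropy
  histogram are the background and tissue modes; a slide whose background
  splits into two strong textural modes could place the valley within the
  background.
* Seam lines and dust specks carry local texture and are picked up as
  thin false-positive structures by design; no morphological cleanup is
  applied.
* Pixel-spacing metadata is not propagated; masks are pure rasters.
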