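"""Unit tests for the local-entropy masking pipeline."""

import numpy as np
import pytest

from entropymask import (
    EntropyHistogram,
    binarize,
    build_entropy_histogram,
    disk_footprint,
    entropy_mask,
    local_entropy_map,
    rgb_to_gray,
    select_entropy_threshold,
)
from entropymask.entropy import _centered_moving_average

from conftest import entropy_oracle


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((0, 0, 0), 0), ((255, 255, 255), 255), ((255, 0, 0), 76), ((0, 255, 0), 150)],
    )
    def test_luma_values(self, rgb, expected):
        img = np.full((2, 2, 3), rgb, dtype=np.uint8)
        assert np.all(rgb_to_gray(img) == expected)

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            rgb_to_gray(np.zeros((4, 4), dtype=np.uint8))


class TestDiskFootprint:
    @pytest.mark.parametrize("radius", [1, 2, 3, 5, 7])
    def test_matches_lattice_point_count(self, radius):
        expected = sum(
            1
            for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if dy * dy + dx * dx <= radius * radius
        )
        assert disk_footprint(radius).sum() == expected

    def test_radius_five_covers_81(self):
        assert disk_footprint(5).sum() == 81

    def test_radius_one_is_cross(self):
        assert disk_footprint(1).sum() == 5

    def test_symmetry_and_center(self):
        fp = disk_footprint(3)
        assert fp[3, 3]  # contains (0, 0)
        assert np.array_equal(fp, fp[::-1, ::-1])  # negation-symmetric

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            disk_footprint(0)


class TestLocalEntropyMap:
    def test_constant_image_is_zero(self):
        for value in (0, 128, 255):
            g = np.full((16, 20), value, dtype=np.uint8)
            assert np.all(local_entropy_map(g, 5) == 0.0)

    @pytest.mark.parametrize("radius", [2, 5])
    def test_matches_bruteforce_oracle(self, rng, radius):
        g = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        np.testing.assert_allclose(
            local_entropy_map(g, radius), entropy_oracle(g, radius), atol=1e-9
        )

    def test_two_value_neighborhood_closed_form(self):
        # craft a footprint whose 81 pixels split 41 / 40 between two values
        fp = disk_footprint(5)
        g = np.zeros((11, 11), dtype=np.uint8)
        ys, xs = np.nonzero(fp)
        g[ys[:41], xs[:41]] = 10
        g[ys[41:], xs[41:]] = 200
        expected = -(41 / 81) * np.log2(41 / 81) - (40 / 81) * np.log2(40 / 81)
        emap = local_entropy_map(g, fp)
        assert emap[5, 5] == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_log2_footprint_size(self, rng):
        g = rng.integers(0, 256, (48, 48), dtype=np.uint8)
        emap = local_entropy_map(g, 5)
        assert emap.min() >= 0.0
        assert emap.max() <= np.log2(81) + 1e-12

    def test_monotone_remap_leaves_map_unchanged(self, rng):
        g = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        # strictly increasing 1-to-1 lookup table over [0, 255]
        lut = np.sort(rng.choice(256, size=256, replace=False)).astype(np.uint8)
        assert np.array_equal(local_entropy_map(g, 5), local_entropy_map(lut[g], 5))

    def test_row_chunking_does_not_change_result(self, rng):
        g = rng.integers(0, 256, (37, 21), dtype=np.uint8)
        a = local_entropy_map(g, 3, row_chunk=5)
        b = local_entropy_map(g, 3, row_chunk=1000)
        assert np.array_equal(a, b)

    def test_interior_agrees_with_skimage_rank_filter(self, rng):
        skfilters = pytest.importorskip("skimage.filters.rank")
        from skimage.morphology import disk as sk_disk

        g = rng.integers(0, 256, (40, 40), dtype=np.uint8)
        mine = local_entropy_map(g, 5)
        theirs = skfilters.entropy(g, sk_disk(5))
        np.testing.assert_allclose(mine[5:-5, 5:-5], theirs[5:-5, 5:-5], atol=1e-9)


def _hist(counts, smoothed=None, edges=None):
    counts = np.asarray(counts)
    if edges is None:
        edges = np.arange(len(counts) + 1, dtype=np.float64)
    if smoothed is None:
        smoothed = counts.astype(np.float64)
    return EntropyHistogram(
        bin_edges=np.asarray(edges, dtype=np.float64),
        counts=counts,
        smoothed_counts=np.asarray(smoothed, dtype=np.float64),
    )


class TestEntropyHistogram:
    def test_all_zero_map_uses_unit_span(self):
        hist = build_entropy_histogram(np.zeros((10, 10)), n_bins=256)
        assert hist.counts[0] == 100
        assert hist.counts[1:].sum() == 0
        assert hist.bin_edges[-1] == 1.0

    def test_counts_conserve_pixel_total(self, rng):
        emap = rng.uniform(0, 6, size=(31, 17))
        hist = build_entropy_histogram(emap, n_bins=64)
        assert hist.counts.sum() == emap.size

    def test_two_spike_map_bins_to_extremes(self):
        # bins span [0, max], so 0.2 falls in bin 0 and the max in bin 9
        emap = np.array([0.2] * 100 + [5.0] * 100).reshape(20, 10)
        hist = build_entropy_histogram(emap, n_bins=10, smooth_window=1)
        assert hist.counts[0] == 100
        assert hist.counts[-1] == 100
        assert hist.counts[1:-1].sum() == 0

    def test_moving_average_shrinks_at_edges(self):
        counts = np.array([0.0, 9, 1, 0, 1, 8, 0])
        sm = _centered_moving_average(counts, 3)
        expected = [0.0, 10 / 3, 10 / 3, 2 / 3, 3.0, 3.0, 0.0]
        np.testing.assert_allclose(sm, expected)


class TestThresholdSelection:
    def test_valley_between_two_modes(self):
        decision = select_entropy_threshold(_hist([0, 9, 1, 0, 1, 8, 0]))
        assert decision.method == "valley_minimum"
        assert decision.valley_bin_index == 3
        assert decision.threshold == pytest.approx(3.5)  # center of bin 3

    def test_plateau_valley_takes_leftmost_bin(self):
        decision = select_entropy_threshold(_hist([5, 0, 0, 0, 7]))
        assert decision.method == "valley_minimum"
        assert decision.valley_bin_index == 1

    def test_deepest_valley_wins(self):
        decision = select_entropy_threshold(_hist([0, 9, 3, 4, 1, 4, 8, 0]))
        assert decision.valley_bin_index == 4

    def test_unimodal_falls_back_to_otsu(self):
        decision = select_entropy_threshold(_hist([1, 5, 9, 5, 1]))
        assert decision.method == "fallback_otsu_on_entropy"
        assert decision.valley_bin_index is None

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            select_entropy_threshold(_hist([0, 0, 0]))


class TestBinarize:
    def test_strict_inequality(self):
        emap = np.array([[0.1, 0.5, 0.9]])
        assert binarize(emap, 0.5).tolist() == [[False, False, True]]

    def test_zero_threshold_on_zero_map_is_background(self):
        assert not binarize(np.zeros((4, 4)), 0.0).any()

    def test_zero_threshold_on_positive_map_is_foreground(self):
        assert binarize(np.full((4, 4), 0.01), 0.0).all()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), -1.0)


class TestEntropyMaskPipeline:
    def test_composition_equals_components(self, rng):
        img = rng.integers(0, 256, (48, 48, 3), dtype=np.uint8)
        result = entropy_mask(img, radius=5, return_details=True)
        gray = rgb_to_gray(img)
        emap = local_entropy_map(gray, disk_footprint(5))
        hist = build_entropy_histogram(emap, n_bins=256, smooth_window=5)
        decision = select_entropy_threshold(hist)
        assert np.array_equal(result.entropy_map, emap)
        assert result.decision == decision
        assert np.array_equal(result.mask, binarize(emap, decision.threshold))

    def test_uniform_white_is_all_background_via_fallback(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        result = entropy_mask(img, return_details=True)
        assert result.decision.method == "fallback_otsu_on_entropy"
        assert not result.mask.any()

    def test_deterministic(self, rng):
        img = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        assert np.array_equal(entropy_mask(img), entropy_mask(img))
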