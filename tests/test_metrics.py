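"""Unit and property tests for mask evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entropymask import (
    ConfusionCounts,
    confusion_counts,
    evaluate_mask,
    false_positive_rate,
    jaccard_index,
    pixel_accuracy,
    sensitivity,
    summarize_benchmark,
)
from entropymask.metrics import MaskMetrics


def test_confusion_counts_all_foreground_agree():
    ones = np.ones((2, 2), dtype=bool)
    c = confusion_counts(ones, ones)
    assert (c.tp, c.fp, c.tn, c.fn) == (4, 0, 0, 0)


def test_confusion_counts_total_disagreement():
    ones = np.ones((2, 2), dtype=bool)
    c = confusion_counts(ones, ~ones)
    assert (c.tp, c.fp, c.tn, c.fn) == (0, 4, 0, 0)
    assert false_positive_rate(c) == 1.0


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion_counts(np.ones((2, 2), dtype=bool), np.ones((3, 2), dtype=bool))


def test_identical_and_disjoint_masks():
    a = np.zeros((4, 4), dtype=bool)
    a[:2] = True
    assert jaccard_index(confusion_counts(a, a)) == 1.0
    assert sensitivity(confusion_counts(a, a)) == 1.0
    assert jaccard_index(confusion_counts(a, ~a)) == 0.0
    assert pixel_accuracy(confusion_counts(a, ~a)) == 0.0


def test_empty_mask_conventions():
    empty = np.zeros((3, 3), dtype=bool)
    full = np.ones((3, 3), dtype=bool)
    with pytest.warns(UserWarning):
        assert jaccard_index(confusion_counts(empty, empty)) == 1.0
    with pytest.warns(UserWarning):
        assert np.isnan(sensitivity(confusion_counts(empty, empty)))
    with pytest.warns(UserWarning):
        assert np.isnan(false_positive_rate(confusion_counts(full, full)))
    # predicted empty on nonempty truth: defined, and zero
    truth = np.zeros((3, 3), dtype=bool)
    truth[0, 0] = True
    assert sensitivity(confusion_counts(empty, truth)) == 0.0


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_random_mask_properties(seed):
    """Counts conserve the pixel total; defined metrics lie in [0, 1];
    Jaccard is symmetric and equals 1 iff the masks are identical."""
    rng = np.random.default_rng(seed)
    shape = (int(rng.integers(1, 12)), int(rng.integers(1, 12)))
    pred = rng.random(shape) < rng.random()
    truth = rng.random(shape) < rng.random()

    c = confusion_counts(pred, truth)
    assert c.total == pred.size

    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # empty-mask conventions may warn
        jac = jaccard_index(c)
        for value in (jac, sensitivity(c), false_positive_rate(c), pixel_accuracy(c)):
            assert np.isnan(value) or 0.0 <= value <= 1.0
        assert jac == jaccard_index(confusion_counts(truth, pred))
        if pred.any() or truth.any():
            assert (jac == 1.0) == np.array_equal(pred, truth)


def test_sensitivity_and_fpr_are_not_symmetric():
    pred = np.zeros((4, 4), dtype=bool)
    truth = np.zeros((4, 4), dtype=bool)
    pred.ravel()[:6] = True
    truth.ravel()[3:7] = True
    c_pt = confusion_counts(pred, truth)
    c_tp = confusion_counts(truth, pred)
    assert sensitivity(c_pt) != sensitivity(c_tp)
    assert false_positive_rate(c_pt) != false_positive_rate(c_tp)
    assert jaccard_index(c_pt) == jaccard_index(c_tp)


def _metrics(j, s, f, a):
    return MaskMetrics(jaccard=j, sensitivity=s, false_positive_rate=f, pixel_accuracy=a)


class TestSummarize:
    def test_single_image_sd_zero(self):
        df = summarize_benchmark([("otsu", _metrics(0.5, 0.6, 0.1, 0.9))])
        row = df.iloc[0]
        assert row["Method"] == "otsu"
        assert row["Jaccard_mean"] == 0.5
        assert row["Jaccard_sd"] == 0.0
        assert row["N"] == 1

    def test_sample_sd_uses_n_minus_one(self):
        df = summarize_benchmark(
            [
                ("entropy", _metrics(0.4, 1, 0, 1)),
                ("entropy", _metrics(0.6, 1, 0, 1)),
            ]
        )
        assert df.iloc[0]["Jaccard_mean"] == pytest.approx(0.5)
        assert df.iloc[0]["Jaccard_sd"] == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_canonical_method_order(self):
        results = [
            ("slidemask", _metrics(1, 1, 0, 1)),
            ("entropy", _metrics(1, 1, 0, 1)),
            ("otsu", _metrics(1, 1, 0, 1)),
        ]
        df = summarize_benchmark(results)
        assert df["Method"].tolist() == ["entropy", "otsu", "slidemask"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_benchmark([])


def test_evaluate_mask_bundles_all_four(rng):
    pred = rng.random((8, 8)) < 0.5
    truth = rng.random((8, 8)) < 0.5
    m = evaluate_mask(pred, truth)
    c = confusion_counts(pred, truth)
    assert m == _metrics(
        jaccard_index(c), sensitivity(c), false_positive_rate(c), pixel_accuracy(c)
    )


def test_confusion_counts_dataclass_total():
    assert ConfusionCounts(tp=1, fp=2, tn=3, fn=4).total == 10
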