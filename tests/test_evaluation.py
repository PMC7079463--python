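import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import loop_pixel_confusion
from spikeseg.evaluation import (
    FN_PINK,
    FP_GREEN,
    ObjectConfusion,
    PixelConfusion,
    counting_metrics,
    error_overlay,
    evaluate_dataset,
    f1_from_precision_recall,
    implied_error_pixels,
    jaccard_from_precision_recall,
    pixel_confusion,
    segmentation_metrics,
)
from spikeseg.reference import (
    COUNTING_AVERAGES,
    COUNTING_ROWS,
    EVAL_PIXELS,
    ILLUMINATION_E1,
    SEGMENTATION_REFERENCE,
)


class TestPixelConfusion:
    def test_identical_masks_have_no_errors(self, rng):
        mask = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        c = pixel_confusion(mask, mask)
        assert c.fp == c.fn == 0
        assert c.tp == int(mask.sum())

    def test_all_predicted_on_empty_truth(self):
        c = pixel_confusion(np.ones((6, 7), dtype=np.uint8),
                            np.zeros((6, 7), dtype=np.uint8))
        assert c.fp == 42 and c.tp == c.tn == c.fn == 0

    def test_matches_per_pixel_loop_oracle(self, rng):
        pred = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        truth = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        c = pixel_confusion(pred, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == loop_pixel_confusion(pred, truth)
        assert c.total == 256

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pixel_confusion(np.zeros((4, 4)), np.zeros((4, 5)))


class TestSegmentationMetrics:
    def test_published_precision_recall_imply_f1_and_ji(self):
        p = SEGMENTATION_REFERENCE["precision"]
        r = SEGMENTATION_REFERENCE["recall"]
        assert round(f1_from_precision_recall(p, r), 4) == \
            SEGMENTATION_REFERENCE["f1"]
        assert round(jaccard_from_precision_recall(p, r), 4) == \
            SEGMENTATION_REFERENCE["ji"]

    def test_perfect_prediction(self):
        m = segmentation_metrics(PixelConfusion(tp=40, tn=60, fp=0, fn=0))
        assert (m.precision, m.recall, m.accuracy, m.f1, m.ji) == (1, 1, 1, 1, 1)
        assert m.e1 == m.e2 == 0.0

    def test_empty_agreement_convention(self):
        m = segmentation_metrics(PixelConfusion(tp=0, tn=100, fp=0, fn=0))
        assert m.precision == m.recall == 1.0

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            segmentation_metrics(PixelConfusion(0, 0, 0, 0))

    @given(tp=st.integers(0, 500), tn=st.integers(0, 500),
           fp=st.integers(0, 500), fn=st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_ji_f1_relations_hold(self, tp, tn, fp, fn):
        c = PixelConfusion(tp=tp, tn=tn, fp=fp, fn=fn)
        if c.total == 0:
            return
        m = segmentation_metrics(c)
        assert m.ji <= m.precision + 1e-12
        assert m.ji <= m.recall + 1e-12
        assert m.f1 == pytest.approx(2 * m.ji / (1 + m.ji))
        assert m.e1 * c.total == pytest.approx(fp + fn)


class TestCountingMetrics:
    @pytest.mark.parametrize("row", COUNTING_ROWS, ids=lambda r: f"plant{r.plant}")
    def test_reproduces_every_published_row(self, row):
        p, _, acc, f1 = counting_metrics(ObjectConfusion(row.tp, row.fp, row.fn))
        assert round(p, 2) == row.precision
        assert round(acc, 2) == row.accuracy
        assert round(f1, 2) == row.f1

    def test_row_15_worked_example(self):
        p, _, acc, f1 = counting_metrics(ObjectConfusion(tp=13, fp=2, fn=1))
        assert (round(p, 2), round(acc, 2), round(f1, 2)) == (0.87, 0.81, 0.90)

    def test_averages_match_published_summary(self):
        ms = [counting_metrics(ObjectConfusion(r.tp, r.fp, r.fn))
              for r in COUNTING_ROWS]
        assert round(np.mean([m[0] for m in ms]), 2) == COUNTING_AVERAGES["precision"]
        assert round(np.mean([m[2] for m in ms]), 2) == COUNTING_AVERAGES["accuracy"]
        assert round(np.mean([m[3] for m in ms]), 2) == COUNTING_AVERAGES["f1"]

    def test_accuracy_equals_object_jaccard(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn = rng.integers(0, 20, 3)
            if tp + fp + fn == 0:
                continue
            _, _, acc, _ = counting_metrics(ObjectConfusion(int(tp), int(fp), int(fn)))
            assert acc == pytest.approx(tp / (tp + fp + fn))

    def test_perfect_counting(self):
        assert counting_metrics(ObjectConfusion(tp=5, fp=0, fn=0)) == (1, 1, 1, 1)

    def test_nonzero_tn_rejected(self):
        with pytest.raises(ValueError, match="TN"):
            ObjectConfusion(tp=1, fp=0, fn=0, tn=1)

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            counting_metrics(ObjectConfusion(0, 0, 0))


class TestImpliedErrorPixels:
    def test_published_baseline_error_implies_105_pixels(self):
        assert implied_error_pixels(SEGMENTATION_REFERENCE["e1"], EVAL_PIXELS) == 105

    def test_darkest_illumination_implies_351_pixels(self):
        assert implied_error_pixels(ILLUMINATION_E1[0.1], EVAL_PIXELS) == 351

    def test_zero_rate(self):
        assert implied_error_pixels(0.0, 12345) == 0

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            implied_error_pixels(1.5, 10)


class TestErrorOverlay:
    def test_perfect_prediction_has_no_colored_pixels(self, rng):
        truth = (rng.random((12, 12)) > 0.7).astype(np.uint8)
        overlay = error_overlay(truth, truth)
        assert not (overlay == FN_PINK).all(axis=-1).any()
        assert not (overlay == FP_GREEN).all(axis=-1).any()

    def test_single_missed_pixel_is_pink(self):
        truth = np.zeros((5, 5), dtype=np.uint8)
        truth[2, 2] = 1
        overlay = error_overlay(np.zeros_like(truth), truth)
        assert (overlay == FN_PINK).all(axis=-1).sum() == 1

    def test_colored_pixels_equal_fp_plus_fn(self, rng):
        pred = (rng.random((20, 20)) > 0.6).astype(np.uint8)
        truth = (rng.random((20, 20)) > 0.6).astype(np.uint8)
        overlay = error_overlay(pred, truth)
        colored = int((overlay == FN_PINK).all(axis=-1).sum()
                      + (overlay == FP_GREEN).all(axis=-1).sum())
        c = pixel_confusion(pred, truth)
        assert colored == c.fp + c.fn


class TestEvaluateDataset:
    def test_single_pair_average_equals_itself(self, rng):
        pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        truth = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        per_image, mean = evaluate_dataset([(pred, truth)])
        assert per_image[0] == mean

    def test_duplicated_pair_leaves_average_unchanged(self, rng):
        pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        truth = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        _, mean1 = evaluate_dataset([(pred, truth)])
        _, mean2 = evaluate_dataset([(pred, truth)] * 2)
        assert mean1 == mean2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no .*pairs"):
            evaluate_dataset([])
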