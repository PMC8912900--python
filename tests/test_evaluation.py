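"""Hit-or-miss scoring, the sensitivity/precision arithmetic, aggregation."""

import numpy as np
import pytest

from nervedetect.evaluation import (
    EvalCounts,
    adjudicate_additional,
    aggregate,
    evaluate_slide,
    match_detections,
    pairwise_agreement,
    precision,
    sample_precision_estimate,
    sensitivity,
)
from nervedetect.reference import (
    SCORER_AGREEMENT_PCT,
    load_reference_counts,
    reference_eval_counts,
)
from nervedetect.types import Annotation, AnnotationSet, Box


class TestMatchDetections:
    def test_multiple_boxes_on_one_annotation_is_one_hit(self):
        anns = AnnotationSet([Annotation(Box(10, 10, 30, 30))])
        boxes = [Box(5, 5, 10, 10), Box(20, 20, 10, 10), Box(30, 30, 15, 15)]
        tp_m, fn, unmatched = match_detections(boxes, anns)
        assert (tp_m, fn) == (1, 0)
        assert unmatched == []

    def test_no_boxes_all_missed(self):
        anns = AnnotationSet([Annotation(Box(i * 20, 0, 10, 10)) for i in range(5)])
        assert match_detections([], anns)[:2] == (0, 5)

    def test_single_pixel_touch_is_a_hit(self):
        anns = AnnotationSet([Annotation(Box(10, 10, 10, 10))])
        tp_m, fn, unmatched = match_detections([Box(19, 19, 10, 10)], anns)
        assert (tp_m, fn) == (1, 0)

    def test_one_box_credits_every_annotation_it_touches(self):
        anns = AnnotationSet(
            [Annotation(Box(0, 0, 10, 10)), Annotation(Box(20, 0, 10, 10))]
        )
        tp_m, fn, _ = match_detections([Box(5, 5, 20, 4)], anns)
        assert (tp_m, fn) == (2, 0)

    def test_non_matching_boxes_returned(self):
        anns = AnnotationSet([Annotation(Box(0, 0, 10, 10))])
        _, _, unmatched = match_detections([Box(50, 50, 5, 5)], anns)
        assert unmatched == [Box(50, 50, 5, 5)]


class TestAdjudicateAdditional:
    def test_truth_nerve_is_tp_a(self):
        truth = np.zeros((100, 100), dtype=bool)
        truth[40:50, 40:50] = True
        tp_a, fp = adjudicate_additional([Box(35, 35, 20, 20)], truth_mask=truth)
        assert (tp_a, fp) == (1, 0)

    def test_background_box_is_fp(self):
        truth = np.zeros((100, 100), dtype=bool)
        tp_a, fp = adjudicate_additional([Box(10, 10, 20, 20)], truth_mask=truth)
        assert (tp_a, fp) == (0, 1)

    def test_empty_list(self):
        assert adjudicate_additional([], truth_mask=np.zeros((5, 5), bool)) == (0, 0)

    def test_requires_some_truth_source(self):
        with pytest.raises(ValueError, match="adjudication"):
            adjudicate_additional([Box(0, 0, 5, 5)])

    def test_explicit_adjudication_list(self):
        tp_a, fp = adjudicate_additional(
            [Box(0, 0, 5, 5), Box(10, 10, 5, 5)], adjudications=[True, False]
        )
        assert (tp_a, fp) == (1, 1)


class TestRates:
    @pytest.mark.parametrize(
        "tp_m, fn, expected",
        [(9, 1, 0.90), (31, 4, 0.89), (8, 0, 1.0)],
    )
    def test_sensitivity_reference_rows(self, tp_m, fn, expected):
        assert round(sensitivity(tp_m, fn), 2) == expected

    def test_sensitivity_undefined_with_no_annotations(self):
        assert sensitivity(0, 0) is None

    @pytest.mark.parametrize(
        "tp_m, tp_a, fp, expected",
        [(9, 34, 16, 0.73), (8, 70, 30, 0.72), (5, 2, 0, 1.0)],
    )
    def test_precision_reference_rows(self, tp_m, tp_a, fp, expected):
        assert round(precision(tp_m, tp_a, fp), 2) == expected

    def test_precision_undefined_with_no_detections(self):
        assert precision(0, 0, 0) is None


class TestAggregate:
    def test_single_slide_passthrough(self):
        counts = EvalCounts(n_annotations=10, TP_m=9, FN=1, TP_a=4, FP=2)
        agg = aggregate([counts])
        assert agg["TPR"] == pytest.approx(0.9)
        assert agg["PPV"] == pytest.approx(13 / 15)

    def test_undefined_tpr_slides_excluded_from_mean(self):
        a = EvalCounts(n_annotations=10, TP_m=5, FN=5, TP_a=0, FP=0)
        b = EvalCounts(n_annotations=0, TP_m=0, FN=0, TP_a=3, FP=1)
        agg = aggregate([a, b])
        assert agg["TPR"] == pytest.approx(0.5)  # slide b contributes nothing
        assert agg["n_annotations"] == 10

    def test_totals_are_sums(self):
        a = EvalCounts(n_annotations=5, TP_m=4, FN=1, TP_a=2, FP=3)
        b = EvalCounts(n_annotations=7, TP_m=6, FN=1, TP_a=1, FP=0)
        agg = aggregate([a, b])
        assert agg["TP_m"] == 10 and agg["TP"] == 13 and agg["FP"] == 3


class TestReferenceTableReproduction:
    """The shipped per-slide reference counts, pushed through the package's
    arithmetic, must reproduce every printed rate to two decimals."""

    @pytest.mark.parametrize("approach", ["cf", "cnn"])
    def test_per_slide_rates(self, approach):
        df = load_reference_counts()
        for counts, (_, row) in zip(reference_eval_counts(approach), df.iterrows()):
            printed_tpr = row[f"{approach}_tpr_printed"]
            printed_ppv = row[f"{approach}_ppv_printed"]
            if np.isnan(printed_tpr):
                assert counts.TPR is None
            else:
                assert round(counts.TPR, 2) == round(float(printed_tpr), 2)
            assert round(counts.PPV, 2) == round(float(printed_ppv), 2)

    def test_overall_means(self):
        cnn = aggregate(reference_eval_counts("cnn"))
        cf = aggregate(reference_eval_counts("cf"))
        assert round(cnn["TPR"], 2) == 0.89
        assert round(cnn["PPV"], 2) == 0.75
        assert round(cf["TPR"], 2) == 0.98
        assert round(cf["PPV"], 2) == 0.09

    def test_overall_totals(self):
        cnn = aggregate(reference_eval_counts("cnn"))
        assert cnn["n_annotations"] == 318
        assert cnn["TP_m"] == 287
        assert cnn["TP"] == 3506
        cf = aggregate(reference_eval_counts("cf"))
        assert cf["TP_m"] == 312
        assert cf["TP"] == 7145


class TestPairwiseAgreement:
    def test_identical_scorers_100(self):
        out = pairwise_agreement([[1, 0, 1], [1, 0, 1]])
        assert out["mean"] == 100.0

    def test_complementary_scorers_0(self):
        out = pairwise_agreement([[1, 0, 1], [0, 1, 0]])
        assert out["mean"] == 0.0

    def test_three_scorers_mean(self):
        """Three scorers over 1000 detections constructed to agree at the
        published pair rates average to the published mean."""
        assert float(np.mean(SCORER_AGREEMENT_PCT)) == pytest.approx(78.3, abs=0.05)
        rngs = np.random.default_rng(0)
        a = rngs.integers(0, 2, 1000)
        flip = lambda v, p: np.where(rngs.random(1000) < p, 1 - v, v)
        out = pairwise_agreement([a, flip(a, 0.2), flip(a, 0.2)])
        assert len(out["pairs"]) == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same"):
            pairwise_agreement([[1, 0], [1]])


class TestSamplePrecisionEstimate:
    def test_small_set_is_exact(self):
        truth = np.zeros((50, 50), dtype=bool)
        truth[10:20, 10:20] = True
        boxes = [Box(12, 12, 5, 5), Box(30, 30, 5, 5)]
        assert sample_precision_estimate(boxes, truth) == (1, 1)

    def test_estimates_scale_to_population(self):
        truth = np.zeros((50, 50), dtype=bool)
        truth[0:25, :] = True
        boxes = [Box(5, 2, 4, 4)] * 300 + [Box(5, 40, 4, 4)] * 100
        tp, fp = sample_precision_estimate(boxes, truth, n_samples=100, seed=1)
        assert tp + fp == 400
        assert 250 <= tp <= 350  # around the true 300


class TestEvaluateSlideOnSynthetic:
    def test_incomplete_annotations_yield_tp_a(self):
        """Detections on truth nerves absent from the expert subset count as
        adjudicated additional true positives, not false positives."""
        from nervedetect.synthetic import SyntheticSpec, generate_slide

        spec = SyntheticSpec(
            image_height_px=512, image_width_px=512, n_nerves=5,
            nerve_area_range_um2=(150.0, 500.0), n_distractors=0,
            annotation_completeness=0.6, seed=5,
        )
        slide = generate_slide(spec)
        # perfect detector: one box per true nerve
        boxes = slide.complete_annotations.boxes()
        counts = evaluate_slide(
            boxes, slide.expert_annotations, truth_mask=slide.truth_mask
        )
        assert counts.TP_m == len(slide.expert_annotations) == 3
        assert counts.TP_a == 2
        assert counts.FP == 0 and counts.FN == 0

    def test_complete_annotations_mean_no_tp_a(self):
        from nervedetect.synthetic import SyntheticSpec, generate_slide

        spec = SyntheticSpec(
            image_height_px=512, image_width_px=512, n_nerves=4,
            nerve_area_range_um2=(150.0, 500.0), n_distractors=0,
            annotation_completeness=1.0, seed=6,
        )
        slide = generate_slide(spec)
        counts = evaluate_slide(
            slide.complete_annotations.boxes(), slide.expert_annotations,
            truth_mask=slide.truth_mask,
        )
        assert counts.TP_a == 0 and counts.FN == 0
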