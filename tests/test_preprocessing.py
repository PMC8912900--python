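"""Training-side pipeline: downsampling, ROI extraction, patch conversion."""

import math

import numpy as np
import pytest

from nervedetect.color_filter import apply_color_filter, rgb_to_hsv_normalised
from nervedetect.preprocessing import (
    ROI,
    TrainingSample,
    block_partition,
    build_training_samples,
    classify_rois,
    downsample,
    exclude_artifact_samples,
    extract_label_mask,
    extract_rois,
    patch_count,
    tile_roi,
    window_starts,
)
from nervedetect.synthetic import SyntheticSpec, generate_slide
from nervedetect.types import Annotation, AnnotationSet, Box, SlideImage


def windows_oracle(dim: int, P: int) -> int:
    """Enumerate the stride-P/2 windows that tile the dimension padded up to
    the next multiple of P (the 50%-overlap grid the patch conversion uses)."""
    padded = math.ceil(dim / P) * P
    return len(range(0, padded - P + 1, P // 2))


def solid_image(h, w, value=128):
    return SlideImage(np.full((h, w, 3), value, dtype=np.uint8))


class TestDownsample:
    def test_output_dims_are_ceil(self):
        out = downsample(solid_image(1000, 998), 4)
        assert out.shape == (250, 250)
        assert out.microns_per_pixel == pytest.approx(2.0)

    def test_constant_image_stays_constant(self):
        out = downsample(solid_image(64, 64, 77), 4)
        assert (out.pixels == 77).all()

    def test_block_mean_hand_computed(self):
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        px[:, :, 0] = np.arange(16).reshape(4, 4) * 10
        out = downsample(SlideImage(px), 4)
        assert out.shape == (1, 1)
        assert out.pixels[0, 0, 0] == round(np.arange(16).mean() * 10)

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample(solid_image(8, 8), 0)


class TestBlockPartition:
    def test_grid_counts_and_sizes(self):
        blocks = block_partition(solid_image(160, 160), grid=16)
        assert len(blocks) == 256
        assert all(b.shape == (10, 10, 3) for _, b in blocks)

    def test_blocks_tile_exactly(self):
        img = solid_image(103, 97)
        blocks = block_partition(img, grid=7)
        cover = np.zeros((103, 97), dtype=int)
        for box, _ in blocks:
            cover[box.slices()] += 1
        assert (cover == 1).all()

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            block_partition(solid_image(130, 8), grid=16)


class TestExtractRois:
    def test_single_blob_one_roi(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:70, 50:70] = True  # 400 px
        assert len(extract_rois(mask)) == 1

    def test_sub_size_blob_dropped(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:60, 50:55] = True  # 50 px, below the >100 px rule
        assert extract_rois(mask) == []

    def test_nearby_blobs_become_one_roi(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:70, 40:50] = True  # 200 px
        mask[50:70, 60:70] = True  # 200 px, 10 px gap
        assert len(extract_rois(mask)) == 1


class TestClassifyRois:
    def setup_method(self):
        self.anns = AnnotationSet([Annotation(Box(10, 10, 20, 20))])
        self.negs = [Box(100, 100, 40, 40)]

    def test_annotation_intersection_is_positive(self):
        (roi,) = classify_rois([ROI(Box(29, 29, 10, 10))], self.anns, self.negs)
        assert roi.label == "positive"  # 1 px overlap suffices

    def test_negative_region_is_negative(self):
        (roi,) = classify_rois([ROI(Box(110, 110, 10, 10))], self.anns, self.negs)
        assert roi.label == "negative"

    def test_neither_is_unlabelled(self):
        (roi,) = classify_rois([ROI(Box(60, 60, 10, 10))], self.anns, self.negs)
        assert roi.label == "unlabelled"

    def test_annotation_wins_over_negative_region(self, caplog):
        anns = AnnotationSet([Annotation(Box(100, 100, 10, 10))])
        with caplog.at_level("WARNING"):
            (roi,) = classify_rois([ROI(Box(105, 105, 10, 10))], anns, self.negs)
        assert roi.label == "positive"
        assert "negative region" in caplog.text


class TestPatchCount:
    @pytest.mark.parametrize("dim, expected", [(160, 1), (320, 3), (400, 5)])
    def test_worked_examples(self, dim, expected):
        assert patch_count(dim, 160) == expected
        assert windows_oracle(dim, 160) == expected

    def test_matches_enumeration_oracle(self):
        for dim in range(161, 1601):
            assert patch_count(dim, 160) == windows_oracle(dim, 160)

    def test_small_dim_yields_one(self):
        assert patch_count(1, 160) == 1
        assert patch_count(159, 160) == 1


class TestTileRoi:
    def test_roi_equal_to_patch_returns_crop(self):
        img = SlideImage(
            np.random.default_rng(0).integers(0, 256, (400, 400, 3), dtype=np.uint8)
        )
        roi = ROI(Box(40, 60, 160, 160))
        ((win, patch),) = tile_roi(roi, img, P=160)
        assert win == Box(40, 60, 160, 160)
        np.testing.assert_array_equal(patch, img.pixels[60:220, 40:200])

    def test_double_size_roi_yields_nine_patches(self):
        img = solid_image(800, 800)
        patches = tile_roi(ROI(Box(100, 100, 320, 320)), img, P=160)
        assert len(patches) == 9

    @pytest.mark.parametrize("w, h", [(1, 1), (80, 200), (333, 47), (1000, 500)])
    def test_patches_exact_size_and_cover_roi(self, w, h):
        img = solid_image(1100, 1100)
        box = Box(30, 50, w, h)
        cover = np.zeros((1100, 1100), dtype=bool)
        for win, patch in tile_roi(ROI(box), img, P=160):
            assert patch.shape == (160, 160, 3)
            cover[win.slices()] = True
        assert cover[box.slices()].all(), "windows must jointly cover the ROI"

    def test_windows_shift_inward_at_border(self):
        img = solid_image(200, 200)
        for win, _ in tile_roi(ROI(Box(150, 150, 50, 50)), img, P=160):
            assert 0 <= win.x0 and win.x1 <= 200
            assert 0 <= win.y0 and win.y1 <= 200

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            window_starts(0, 50, 160, 100)


class TestExtractLabelMask:
    def test_label_requires_colour_and_annotation(self):
        patch = np.full((8, 8, 3), 255, dtype=np.uint8)
        patch[2:4, 2:4] = (150, 92, 43)  # brown, in range
        patch[5:7, 5:7] = (150, 92, 43)
        ann = np.zeros((8, 8), dtype=bool)
        ann[0:4, 0:4] = True  # covers the first brown block only
        label = extract_label_mask(patch, ann)
        assert label[2:4, 2:4].all()  # brown AND annotated -> positive
        assert not label[5:7, 5:7].any()  # brown outside annotation -> negative
        assert not label[0, 0]  # annotated but white -> negative


class TestExcludeArtifactSamples:
    def _sample(self, outside_blob: bool) -> TrainingSample:
        patch = np.full((64, 64, 3), 245, dtype=np.uint8)
        ann = np.zeros((64, 64), dtype=bool)
        ann[8:24, 8:24] = True
        patch[10:20, 10:20] = (150, 92, 43)  # in-annotation nerve stain
        if outside_blob:
            patch[45:60, 45:60] = (150, 92, 43)  # artifact blob far outside
        fired = apply_color_filter(rgb_to_hsv_normalised(patch))
        return TrainingSample(
            image_patch=patch, label_mask=fired & ann,
            class_label="positive", annotation_mask=ann,
        )

    def test_clean_sample_kept(self):
        assert len(exclude_artifact_samples([self._sample(False)])) == 1

    def test_artifact_dominated_sample_dropped(self):
        assert exclude_artifact_samples([self._sample(True)]) == []

    def test_empty_input(self):
        assert exclude_artifact_samples([]) == []

    def test_explicit_exclusion_list(self):
        samples = [self._sample(False), self._sample(False)]
        kept = exclude_artifact_samples(samples, explicit_exclusions={0})
        assert kept == [samples[1]]


class TestEndToEndSampleBuilding:
    def test_complete_annotations_yield_positive_rois(self):
        """Every nerve above the size rule on a distractor-free slide becomes
        at least one positive sample; with full annotation completeness and
        no distractors there are no artifact exclusions."""
        spec = SyntheticSpec(
            image_height_px=512, image_width_px=512, n_nerves=4,
            nerve_area_range_um2=(100.0, 400.0), n_distractors=0,
            annotation_completeness=1.0, seed=21,
        )
        slide = generate_slide(spec)
        samples = build_training_samples(
            slide.image, slide.expert_annotations, slide.negative_regions, P=64
        )
        assert all(s.class_label == "positive" for s in samples)
        assert len(samples) >= 4
        for s in samples:
            assert s.label_mask.any()

    def test_negative_samples_have_empty_labels(self):
        spec = SyntheticSpec(
            image_height_px=512, image_width_px=512, n_nerves=2,
            nerve_area_range_um2=(100.0, 400.0), n_distractors=8,
            annotation_completeness=1.0, seed=22,
        )
        slide = generate_slide(spec)
        samples = build_training_samples(
            slide.image, slide.expert_annotations, slide.negative_regions, P=64
        )
        negatives = [s for s in samples if s.class_label == "negative"]
        assert negatives
        for s in negatives:
            assert not s.label_mask.any()
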