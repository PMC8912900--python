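"""Training-side pipeline: downsampling, ROI extraction, patch conversion.

The flow mirrors the detection pipeline's front end: the slide is reduced to a
working resolution, the brown-stain colour filter proposes candidate regions,
a 20 x 20 closing and the 100 px size rule turn them into ROIs, the ROIs are
labelled positive (intersects an expert annotation) or negative (lies in a
declared negative region), and each ROI is cut into 50%-overlapping P x P
patches that feed the network together with colour-filter-derived pixel-wise
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal
import logging
import math

import numpy as np

from .color_filter import ColorFilterRange, apply_color_filter, rgb_to_hsv_normalised
from .mask_ops import (
    connected_components,
    filter_min_area,
    merge_overlapping_boxes,
    morphological_close,
)
from .types import AnnotationSet, Box, SlideImage

__all__ = [
    "ROI",
    "TrainingSample",
    "downsample",
    "block_partition",
    "extract_rois",
    "classify_rois",
    "patch_count",
    "window_starts",
    "tile_roi",
    "extract_label_mask",
    "exclude_artifact_samples",
    "build_training_samples",
]

logger = logging.getLogger(__name__)

ROILabel = Literal["positive", "negative", "unlabelled"]


@dataclass(frozen=True)
class ROI:
    """A candidate region at working resolution, optionally class-labelled."""

    box: Box
    label: ROILabel = "unlabelled"


@dataclass
class TrainingSample:
    """One network input: an RGB patch, its pixel labels and class label."""

    image_patch: np.ndarray  # (P, P, 3) uint8
    label_mask: np.ndarray  # (P, P) bool; all-false for negative samples
    class_label: Literal["positive", "negative"]
    annotation_mask: np.ndarray | None = None  # patch-frame annotation raster


def downsample(image: SlideImage, factor: int = 4) -> SlideImage:
    """Block-mean (area) downsampling by an integer factor.

    Output dimensions are ``ceil(dim / factor)``; the raster is edge-padded to
    a multiple of the factor first so border blocks keep sensible colours.
    """
    if factor < 1:
        raise ValueError("downsample factor must be >= 1")
    if factor == 1:
        return image
    h, w = image.shape
    ph = (-h) % factor
    pw = (-w) % factor
    px = np.pad(image.pixels, ((0, ph), (0, pw), (0, 0)), mode="edge").astype(float)
    hh, ww = px.shape[0] // factor, px.shape[1] // factor
    out = px.reshape(hh, factor, ww, factor, 3).mean(axis=(1, 3))
    return SlideImage(
        pixels=np.clip(np.round(out), 0, 255).astype(np.uint8),
        microns_per_pixel=image.microns_per_pixel * factor,
        slide_id=image.slide_id,
    )


def block_partition(image: SlideImage, grid: int = 16) -> list[tuple[Box, np.ndarray]]:
    """Split the raster into a ``grid x grid`` set of non-overlapping blocks.

    Blocks tile the image exactly; the last row/column may be smaller. With
    the default grid a ~10,000 px working raster yields 256 blocks of roughly
    625 x 625 px.
    """
    if grid < 1:
        raise ValueError("grid must be >= 1")
    h, w = image.shape
    if h < grid or w < grid:
        raise ValueError(f"image {h}x{w} is smaller than the {grid}x{grid} grid")
    ys = np.linspace(0, h, grid + 1, dtype=int)
    xs = np.linspace(0, w, grid + 1, dtype=int)
    blocks = []
    for i in range(grid):
        for j in range(grid):
            box = Box(int(xs[j]), int(ys[i]), int(xs[j + 1] - xs[j]), int(ys[i + 1] - ys[i]))
            blocks.append((box, image.pixels[box.slices()]))
    return blocks


def extract_rois(
    filter_mask: np.ndarray,
    closing_kernel: tuple[int, int] = (20, 20),
    min_area_px: int = 100,
) -> list[ROI]:
    """Colour-filter mask -> candidate ROIs.

    Closing (20 x 20) combines nearby brown stains, components above the
    100 px size rule become boxes, and boxes that overlap at all are combined
    into a single larger ROI (any positive intersection, unlike the 50% rule
    used in detection post-processing).
    """
    closed = morphological_close(filter_mask, *closing_kernel)
    instances = filter_min_area(connected_components(closed), min_area_px)
    boxes = merge_overlapping_boxes([inst.box for inst in instances],
                                    min_overlap_frac=1e-9)
    return [ROI(box=b) for b in boxes]


def classify_rois(
    rois: list[ROI],
    expert_annotations: AnnotationSet,
    negative_regions: list[Box],
) -> list[ROI]:
    """Label ROIs positive/negative/unlabelled by intersection.

    Any positive-area overlap with an expert annotation makes an ROI positive;
    otherwise any overlap with a declared negative region makes it negative;
    ROIs touching neither stay unlabelled and are excluded from training. An
    ROI overlapping both is labelled positive with a warning.
    """
    ann_boxes = expert_annotations.boxes()
    labelled = []
    for roi in rois:
        hits_ann = any(roi.box.intersects(b) for b in ann_boxes)
        hits_neg = any(roi.box.intersects(b) for b in negative_regions)
        if hits_ann and hits_neg:
            logger.warning(
                "ROI %s overlaps both an annotation and a negative region; "
                "labelling positive", roi.box
            )
        label: ROILabel = (
            "positive" if hits_ann else "negative" if hits_neg else "unlabelled"
        )
        labelled.append(replace(roi, label=label))
    return labelled


def patch_count(dim_px: int, P: int = 160) -> int:
    """Number of 50%-overlapping windows of side P needed to cover ``dim_px``.

    ``ceil(dim/P) * 2 - 1`` for dimensions larger than one patch, else 1.
    """
    if dim_px <= 0 or P <= 0:
        raise ValueError("dimensions must be positive")
    if dim_px <= P:
        return 1
    return math.ceil(dim_px / P) * 2 - 1


def window_starts(start: int, dim_px: int, P: int, limit: int) -> list[int]:
    """Start offsets of the stride-P/2 windows covering ``[start, start+dim_px)``.

    Windows are anchored at ``start``; any window that would leave ``[0,
    limit)`` is shifted inward rather than padded or resampled. A region
    smaller than P yields a single window centred on it (shifted inward at
    borders).
    """
    if P > limit:
        raise ValueError(f"patch size {P} exceeds raster extent {limit}")
    n = patch_count(dim_px, P)
    if dim_px <= P:
        anchors = [start - (P - dim_px) // 2]
    else:
        anchors = [start + i * (P // 2) for i in range(n)]
    return [min(max(a, 0), limit - P) for a in anchors]


def tile_roi(
    roi: ROI | Box, image: SlideImage, P: int = 160
) -> list[tuple[Box, np.ndarray]]:
    """Cut an ROI into 50%-overlapping P x P patches, never resampling.

    Returns ``(window, patch)`` pairs; every patch is exactly P x P, windows
    jointly cover the ROI box, and edge windows are shifted inward to stay on
    the raster.
    """
    box = roi.box if isinstance(roi, ROI) else roi
    h, w = image.shape
    xs = window_starts(box.x0, box.width, P, w)
    ys = window_starts(box.y0, box.height, P, h)
    out = []
    for y in ys:
        for x in xs:
            win = Box(x, y, P, P)
            out.append((win, image.pixels[win.slices()]))
    return out


def extract_label_mask(
    patch: np.ndarray,
    annotation_mask: np.ndarray,
    filter_range: ColorFilterRange | None = None,
) -> np.ndarray:
    """Pixel-wise segmentation labels for one patch.

    A pixel is positive iff it is brown (inside the colour-filter range) AND
    lies inside an annotation; everything else is negative.
    """
    fired = apply_color_filter(rgb_to_hsv_normalised(patch), filter_range)
    return fired & np.asarray(annotation_mask, dtype=bool)


def exclude_artifact_samples(
    samples: list[TrainingSample],
    max_outside_frac: float = 0.3,
    closing_kernel: tuple[int, int] = (20, 20),
    filter_range: ColorFilterRange | None = None,
    explicit_exclusions: set[int] | None = None,
) -> list[TrainingSample]:
    """Drop positive samples dominated by label artifacts.

    A label artifact is colour-filter-positive signal outside the (dilated)
    annotation: blobs or scattered stain that would teach the network wrong
    labels. A positive sample is dropped when such outside signal exceeds
    ``max_outside_frac`` of all its filter-positive pixels. An explicit index
    set can be supplied to mimic manual curation.
    """
    explicit_exclusions = explicit_exclusions or set()
    kept = []
    for i, s in enumerate(samples):
        if i in explicit_exclusions:
            continue
        if s.class_label != "positive" or s.annotation_mask is None:
            kept.append(s)
            continue
        fired = apply_color_filter(rgb_to_hsv_normalised(s.image_patch), filter_range)
        total = int(fired.sum())
        if total == 0:
            kept.append(s)
            continue
        dilated = morphological_close(s.annotation_mask, *closing_kernel)
        outside = int((fired & ~dilated).sum())
        if outside / total <= max_outside_frac:
            kept.append(s)
    return kept


def build_training_samples(
    image: SlideImage,
    expert_annotations: AnnotationSet,
    negative_regions: list[Box],
    P: int = 160,
    downsample_factor: int = 1,
    filter_range: ColorFilterRange | None = None,
    drop_artifacts: bool = True,
) -> list[TrainingSample]:
    """Full training-side pipeline for one slide.

    Downsample to working resolution, colour-filter, extract and classify
    ROIs, tile each labelled ROI into P x P patches, attach pixel labels
    (positive samples) or all-false labels (negative samples), and drop
    artifact-dominated positives.
    """
    work = downsample(image, downsample_factor)
    scale = 1.0 / downsample_factor
    anns = expert_annotations.scaled(scale) if downsample_factor > 1 else expert_annotations
    negs = (
        [b.scaled(scale) for b in negative_regions]
        if downsample_factor > 1
        else list(negative_regions)
    )
    hsv = rgb_to_hsv_normalised(work)
    fired = apply_color_filter(hsv, filter_range)
    rois = classify_rois(extract_rois(fired), anns, negs)
    ann_raster = anns.rasterise(work.shape)
    samples: list[TrainingSample] = []
    for roi in rois:
        if roi.label == "unlabelled":
            continue
        for win, patch in tile_roi(roi, work, P):
            ann_patch = ann_raster[win.slices()]
            if roi.label == "positive":
                label = extract_label_mask(patch, ann_patch, filter_range)
            else:
                label = np.zeros((P, P), dtype=bool)
            samples.append(
                TrainingSample(
                    image_patch=patch.copy(),
                    label_mask=label,
                    class_label=roi.label,
                    annotation_mask=ann_patch.copy(),
                )
            )
    if drop_artifacts:
        samples = exclude_artifact_samples(samples, filter_range=filter_range)
    return samples
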