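"""Whole-slide inference and post-processing into counted nerve instances.

Inference slides a 50%-overlapping P x P window over the working-resolution
raster, runs every window through the gated U-Net, stitches the gated
probabilities by per-pixel maximum (equivalent to OR on the binarised maps,
so overlap never loses detections) and thresholds strictly above 0.5.

Post-processing then applies the counting rules: a 20 x 20 closing combines
predicted positives closer than 20 px, each remaining component gets its
minimal bounding box, instances of 100 px or less are omitted, and boxes
overlapping by at least 50% (intersection over the smaller box) are combined
and counted as one.
"""

from __future__ import annotations

import numpy as np

from .mask_ops import (
    connected_components,
    filter_min_area,
    merge_overlapping_boxes,
    morphological_close,
)
from .model import GatedUNet
from .preprocessing import window_starts
from .types import DetectionResult, SlideImage

__all__ = ["sliding_window_predict", "postprocess", "detect"]


def sliding_window_predict(
    slide: SlideImage,
    model: GatedUNet,
    P: int | None = None,
    batch_size: int = 16,
    threshold: float = 0.5,
) -> np.ndarray:
    """Stitched binary prediction mask for a whole slide.

    Windows advance by P/2 in each dimension (edge windows shifted inward; a
    slide smaller than P is rejected by the window computation). Overlapping
    gated probabilities combine per pixel by maximum before the strict
    ``> threshold`` binarisation.
    """
    P = P or model.config.input_size[0]
    h, w = slide.shape
    ys = window_starts(0, h, P, h)
    xs = window_starts(0, w, P, w)
    prob = np.zeros((h, w), dtype=np.float32)
    coords = [(y, x) for y in ys for x in xs]
    pixels = slide.pixels.astype(np.float32) / 255.0
    for i in range(0, len(coords), batch_size):
        chunk = coords[i : i + batch_size]
        batch = np.stack([pixels[y : y + P, x : x + P] for y, x in chunk])
        _, _, gated = model.predict(batch)
        for (y, x), g in zip(chunk, gated):
            np.maximum(prob[y : y + P, x : x + P], g,
                       out=prob[y : y + P, x : x + P])
    return prob > threshold


def postprocess(
    mask: np.ndarray,
    slide_id: str = "slide",
    closing_kernel: tuple[int, int] = (20, 20),
    min_area_px: int = 100,
    min_overlap_frac: float = 0.5,
    scale_to_full: float = 1.0,
) -> DetectionResult:
    """Turn a binary prediction mask into counted nerve instances.

    ``scale_to_full`` > 1 maps the final boxes back to full-resolution slide
    coordinates when the mask was produced at a downsampled working
    resolution.
    """
    closed = morphological_close(mask, *closing_kernel)
    instances = filter_min_area(connected_components(closed), min_area_px)
    boxes = merge_overlapping_boxes([inst.box for inst in instances],
                                    min_overlap_frac)
    if scale_to_full != 1.0:
        boxes = [b.scaled(scale_to_full) for b in boxes]
    return DetectionResult(slide_id=slide_id, boxes=boxes, stitched_mask=closed)


def detect(
    slide: SlideImage,
    model: GatedUNet,
    P: int | None = None,
    downsample_factor: int = 1,
) -> DetectionResult:
    """End-to-end detection: optional downsampling, sliding-window inference,
    post-processing; boxes are reported in full-resolution coordinates."""
    from .preprocessing import downsample

    work = downsample(slide, downsample_factor)
    mask = sliding_window_predict(work, model, P)
    return postprocess(mask, slide_id=slide.slide_id,
                       scale_to_full=float(downsample_factor))
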