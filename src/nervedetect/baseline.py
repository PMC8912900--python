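"""Colour-filter-only detector (the APR-CF comparator).

The simplest automatic approach: every pixel inside the brown HSV range is a
predicted positive, followed by exactly the same post-processing chain as the
CNN pipeline (closing, size rule, box merging). It shares every constant with
the model-based detector so a head-to-head comparison isolates the model's
contribution: the colour filter is maximally sensitive to brown stain but
cannot reject in-range non-specific staining, which is what costs it
precision.
"""

from __future__ import annotations

from .color_filter import ColorFilterRange, apply_color_filter, rgb_to_hsv_normalised
from .detection import postprocess
from .preprocessing import downsample
from .types import DetectionResult, SlideImage

__all__ = ["colour_filter_detect"]


def colour_filter_detect(
    slide: SlideImage,
    filter_range: ColorFilterRange | None = None,
    downsample_factor: int = 1,
) -> DetectionResult:
    """Detect nerves with the colour filter alone."""
    work = downsample(slide, downsample_factor)
    mask = apply_color_filter(rgb_to_hsv_normalised(work), filter_range)
    return postprocess(mask, slide_id=slide.slide_id,
                       scale_to_full=float(downsample_factor))
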