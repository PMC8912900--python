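"""Binary morphology, connected components and box merging.

These primitives serve two stages: ROI extraction on the training side and
post-processing of model predictions into counted nerve instances. The key
constants come from the detection criteria: a 20 x 20 px closing bridges
nearby axon profiles into one instance, and instances of 100 px or less
(25 um^2 at 0.5 um/px) are discarded as indistinguishable from non-specific
staining.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import Box, Instance

__all__ = [
    "morphological_close",
    "connected_components",
    "filter_min_area",
    "merge_overlapping_boxes",
    "box_overlap_fraction",
]

# 8-connectivity: thin diagonal axonal profiles must not fragment.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def morphological_close(
    mask: np.ndarray, kernel_h: int = 20, kernel_w: int = 20
) -> np.ndarray:
    """Morphological closing with a rectangular structuring element.

    Dilation followed by erosion using the same ``kernel_h x kernel_w`` flat
    rectangle. The input is padded with False by the kernel size before the
    operation so the closing is extensive (output is a superset of the input)
    and idempotent, including at raster borders; nothing is hallucinated
    outside the original extent beyond what a true closing produces.
    """
    if kernel_h < 1 or kernel_w < 1:
        raise ValueError("kernel dimensions must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {mask.shape}")
    if not mask.any():
        return mask.copy()
    pad = (kernel_h, kernel_w)
    padded = np.pad(mask, ((pad[0], pad[0]), (pad[1], pad[1])))
    dil = ndimage.maximum_filter(
        padded, size=(kernel_h, kernel_w), mode="constant", cval=False
    )
    # An even-sized window in scipy is anchored half a pixel off-centre; the
    # erosion origin must be shifted by -1 on even axes so that dilation and
    # erosion use the same translate set (otherwise the result is not a
    # closing: extensivity and idempotence fail).
    origin = (-1 if kernel_h % 2 == 0 else 0, -1 if kernel_w % 2 == 0 else 0)
    ero = ndimage.minimum_filter(
        dil, size=(kernel_h, kernel_w), mode="constant", cval=False, origin=origin
    )
    return ero[pad[0] : -pad[0], pad[1] : -pad[1]]


def connected_components(mask: np.ndarray) -> list[Instance]:
    """Label a mask with 8-connectivity and return one Instance per component.

    Each instance carries its pixel area and minimal axis-aligned bounding box.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    slices = ndimage.find_objects(labels)
    out = []
    for i, (sl, area) in enumerate(zip(slices, areas), start=1):
        ys, xs = sl
        box = Box(xs.start, ys.start, xs.stop - xs.start, ys.stop - ys.start)
        out.append(Instance(pixel_area=int(area), box=box, label=i))
    return out


def filter_min_area(
    instances: list[Instance], min_area_px: int = 100
) -> list[Instance]:
    """Keep instances whose pixel area is strictly greater than ``min_area_px``.

    The size criterion is "greater than" 100 px, so an instance of exactly
    100 px is removed.
    """
    if min_area_px < 0:
        raise ValueError("min_area_px must be non-negative")
    return [inst for inst in instances if inst.pixel_area > min_area_px]


def box_overlap_fraction(a: Box, b: Box, mode: str = "min") -> float:
    """Overlap fraction between two boxes.

    ``mode='min'`` (default) divides the intersection by the smaller box's
    area, so a small box fully contained in a large one scores 1.0;
    ``mode='iou'`` uses intersection-over-union.
    """
    inter = a.intersection_area(b)
    if inter == 0:
        return 0.0
    if mode == "min":
        return inter / min(a.area, b.area)
    if mode == "iou":
        return inter / (a.area + b.area - inter)
    raise ValueError(f"unknown overlap mode {mode!r}")


def merge_overlapping_boxes(
    boxes: list[Box], min_overlap_frac: float = 0.5, mode: str = "min"
) -> list[Box]:
    """Merge boxes that overlap by at least ``min_overlap_frac``.

    Any pair whose overlap fraction (intersection over the smaller box by
    default) reaches the threshold is replaced by its union bounding box;
    merging repeats until no pair qualifies, so the result is a fixed point.
    Pairs below the threshold stay separate and are counted as two individual
    nerves. Boxes are processed in ascending (x0, y0) order, which makes the
    fixed point deterministic and, in practice, independent of input order.
    """
    if not 0.0 < min_overlap_frac <= 1.0:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    current = sorted(boxes, key=lambda b: (b.x0, b.y0, b.x1, b.y1))
    changed = True
    while changed:
        changed = False
        merged: list[Box] = []
        consumed = [False] * len(current)
        for i, a in enumerate(current):
            if consumed[i]:
                continue
            acc = a
            for j in range(i + 1, len(current)):
                if consumed[j]:
                    continue
                if box_overlap_fraction(acc, current[j], mode) >= min_overlap_frac:
                    acc = acc.union(current[j])
                    consumed[j] = True
                    changed = True
            merged.append(acc)
        current = sorted(merged, key=lambda b: (b.x0, b.y0, b.x1, b.y1))
    return current
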