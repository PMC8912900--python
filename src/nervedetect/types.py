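"""Core value types shared by every pipeline stage.

Coordinate conventions: rasters are indexed ``[row, col]`` (y, x), 0-based.
Boxes are axis-aligned and half-open: a :class:`Box` covers the pixel set
``[x0, x0 + width) x [y0, y0 + height)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Box",
    "SlideImage",
    "Annotation",
    "AnnotationSet",
    "Instance",
    "DetectionResult",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned, half-open pixel box ``[x0, x0+w) x [y0, y0+h)``."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"box must have positive size, got {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"box origin must be non-negative, got {self}")

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "Box") -> int:
        iw = min(self.x1, other.x1) - max(self.x0, other.x0)
        ih = min(self.y1, other.y1) - max(self.y0, other.y0)
        return max(iw, 0) * max(ih, 0)

    def intersects(self, other: "Box") -> bool:
        return self.intersection_area(other) > 0

    def union(self, other: "Box") -> "Box":
        x0 = min(self.x0, other.x0)
        y0 = min(self.y0, other.y0)
        return Box(x0, y0, max(self.x1, other.x1) - x0, max(self.y1, other.y1) - y0)

    def scaled(self, factor: float) -> "Box":
        """Scale to another resolution, rounding outward (floor origin, ceil end)."""
        x0 = int(np.floor(self.x0 * factor))
        y0 = int(np.floor(self.y0 * factor))
        x1 = int(np.ceil(self.x1 * factor))
        y1 = int(np.ceil(self.y1 * factor))
        return Box(x0, y0, max(x1 - x0, 1), max(y1 - y0, 1))

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices for indexing a raster."""
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.width, self.height)


@dataclass
class SlideImage:
    """An RGB raster plus its physical scale in microns per pixel."""

    pixels: np.ndarray  # (H, W, 3) uint8
    microns_per_pixel: float = 0.5
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected (H, W, 3) RGB raster, got shape {self.pixels.shape}"
            )
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def area_px(self, area_um2: float) -> float:
        """Convert a physical area in square microns to pixels at this scale."""
        return area_um2 / self.microns_per_pixel**2


@dataclass(frozen=True)
class Annotation:
    """A coarse object annotation: a labelled box on a slide."""

    box: Box
    label: str = "nerve"


class AnnotationSet:
    """An ordered collection of annotations for one slide."""

    def __init__(self, annotations: Sequence[Annotation] = (), slide_id: str = "slide"):
        self.annotations: list[Annotation] = list(annotations)
        self.slide_id = slide_id

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.annotations)

    def __getitem__(self, i: int) -> Annotation:
        return self.annotations[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.annotations == other.annotations

    def boxes(self) -> list[Box]:
        return [a.box for a in self.annotations]

    def subset(self, indices: Sequence[int]) -> "AnnotationSet":
        return AnnotationSet([self.annotations[i] for i in indices], self.slide_id)

    def scaled(self, factor: float) -> "AnnotationSet":
        return AnnotationSet(
            [Annotation(a.box.scaled(factor), a.label) for a in self.annotations],
            self.slide_id,
        )

    def rasterise(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean raster with True inside any annotation box."""
        mask = np.zeros(shape, dtype=bool)
        h, w = shape
        for a in self.annotations:
            ys = slice(min(a.box.y0, h), min(a.box.y1, h))
            xs = slice(min(a.box.x0, w), min(a.box.x1, w))
            mask[ys, xs] = True
        return mask

    def __repr__(self) -> str:
        return f"AnnotationSet({len(self)} annotations, slide_id={self.slide_id!r})"


@dataclass(frozen=True)
class Instance:
    """A connected component of a binary mask with its minimal bounding box."""

    pixel_area: int
    box: Box
    label: int = 0

    def __post_init__(self) -> None:
        if self.pixel_area > self.box.area:
            raise ValueError("pixel_area cannot exceed box area")


@dataclass
class DetectionResult:
    """Final counted nerve detections for one slide."""

    slide_id: str
    boxes: list[Box] = field(default_factory=list)
    stitched_mask: np.ndarray | None = None

    @property
    def count(self) -> int:
        return len(self.boxes)
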