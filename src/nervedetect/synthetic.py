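"""Seedable generator of IHC-like RGB tiles with known nerve ground truth.

Real slides are PGP9.5/DAB stained thyroid sections: nerves render as brown
(hue ~0.04-0.2 in normalised HSV) structures of widely varying size and form
against a pale background with blue-purple haematoxylin-counterstained nuclei,
plus non-specific brown staining that the detector must reject. No public
dataset accompanies those slides, so every downstream stage is exercised on
synthetic tiles that emulate the relevant properties:

* nerves painted strictly inside the default colour-filter range, in four
  appearance classes — a single connected formation, separated small
  formations, separated clusters (both with gaps under 20 px so one 20 x 20
  closing unifies them), and a low-gradient "smudge";
* distractors split between in-range blobs (small ones below the 100 px size
  criterion and larger diffuse low-saturation washes that a colour filter
  cannot reject) and brown-ish blobs outside the filter range;
* a "complete" annotation set covering every nerve and a deliberately
  incomplete "expert" subset, mimicking coarse manual annotation;
* negative regions guaranteed nerve-free, from which negative training
  samples are drawn.

All painted objects are kept pairwise more than 20 px apart so the closing
step never merges distinct objects; object counts therefore stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.color import hsv2rgb
from skimage.draw import ellipse as draw_ellipse

from .color_filter import ColorFilterRange
from .types import Annotation, AnnotationSet, Box, SlideImage

__all__ = [
    "APPEARANCE_KINDS",
    "SyntheticSpec",
    "SyntheticSlide",
    "paint_appearance",
    "generate_slide",
]

APPEARANCE_KINDS = ("single", "separated_small", "separated_clusters", "smudge")

# Nerve colours are sampled strictly inside the default filter range
# (0.04, 0.2, 0.4)-(0.2, 1, 1) with a safety margin that survives uint8
# quantisation, so label extraction is consistent by construction.
_NERVE_H = (0.06, 0.18)
_NERVE_S = (0.45, 0.90)
_NERVE_V = (0.45, 0.90)
_SMUDGE_S = (0.30, 0.50)

# Objects are separated by more than the closing kernel plus the negative
# region margin, so a 20x20 closing never bridges two distinct objects and a
# closing-grown nerve ROI can never reach into a negative region.
_MIN_GAP_PX = 34
_BORDER_MARGIN = 8


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic slide.

    ``appearance_mix`` gives sampling proportions over the four appearance
    classes and must sum to 1. ``annotation_completeness`` is the fraction of
    nerves included in the "expert" annotation subset; the complete set always
    covers every nerve. Areas are physical (um^2) and converted to pixels via
    ``microns_per_pixel`` (default 0.5, so 25 um^2 corresponds to 100 px).
    """

    image_height_px: int = 768
    image_width_px: int = 768
    microns_per_pixel: float = 0.5
    n_nerves: int = 8
    nerve_area_range_um2: tuple[float, float] = (25.0, 22500.0)
    appearance_mix: dict[str, float] = field(
        default_factory=lambda: {
            "single": 0.4,
            "separated_small": 0.2,
            "separated_clusters": 0.2,
            "smudge": 0.2,
        }
    )
    n_distractors: int = 8
    annotation_completeness: float = 1.0
    seed: int = 0
    allow_small_nerves: bool = False  # permit a lower area bound below 25 um^2

    def __post_init__(self) -> None:
        if self.image_height_px < 128 or self.image_width_px < 128:
            raise ValueError("synthetic slides must be at least 128 px per side")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.n_nerves < 0 or self.n_distractors < 0:
            raise ValueError("object counts must be non-negative")
        lo, hi = self.nerve_area_range_um2
        if lo <= 0 or hi < lo:
            raise ValueError("nerve_area_range_um2 must be positive and ordered")
        if lo < 25.0 and not self.allow_small_nerves:
            raise ValueError(
                "nerve areas below 25 um^2 are below the detection size "
                "criterion; set allow_small_nerves=True to override"
            )
        unknown = set(self.appearance_mix) - set(APPEARANCE_KINDS)
        if unknown:
            raise ValueError(f"unknown appearance kinds: {sorted(unknown)}")
        total = float(sum(self.appearance_mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"appearance_mix must sum to 1, got {total}")
        if not 0.0 <= self.annotation_completeness <= 1.0:
            raise ValueError("annotation_completeness must be in [0, 1]")


@dataclass
class SyntheticSlide:
    """A generated tile with its full ground truth."""

    image: SlideImage
    truth_mask: np.ndarray  # union of all nerve pixels
    complete_annotations: AnnotationSet
    expert_annotations: AnnotationSet  # subset of complete_annotations
    negative_regions: list[Box]
    nerve_kinds: list[str] = field(default_factory=list)
    nerve_areas_px: list[int] = field(default_factory=list)
    distractor_boxes: list[Box] = field(default_factory=list)
    distractor_kinds: list[str] = field(default_factory=list)


def _blob_mask(
    shape: tuple[int, int],
    cy: float,
    cx: float,
    area: float,
    aspect: float,
    angle: float,
) -> np.ndarray:
    """Rasterise one ellipse of the requested pixel area into a boolean mask."""
    a = np.sqrt(area * aspect / np.pi)
    b = np.sqrt(area / (aspect * np.pi))
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=angle)
    mask[rr, cc] = True
    return mask


def _sample_nerve_hsv(rng: np.random.Generator, smudge: bool) -> tuple[float, ...]:
    h = rng.uniform(*_NERVE_H)
    s = rng.uniform(*(_SMUDGE_S if smudge else _NERVE_S))
    v = rng.uniform(*_NERVE_V)
    return h, s, v


def _textured_colour(
    mask: np.ndarray, base: tuple[float, ...], rng: np.random.Generator, smooth: bool
) -> np.ndarray:
    """Per-pixel HSV values for the painted pixels, clipped inside the nerve box.

    Non-smudge nerves get speckled value/saturation texture (axon profiles and
    perineurium read as focal, discrete staining); smudges stay smooth so their
    saturation gradient is low.
    """
    n = int(mask.sum())
    h0, s0, v0 = base
    if smooth:
        jitter_s = rng.normal(0.0, 0.01, n)
        jitter_v = rng.normal(0.0, 0.01, n)
    else:
        jitter_s = rng.normal(0.0, 0.08, n)
        jitter_v = rng.normal(0.0, 0.12, n) - 0.08 * (rng.random(n) < 0.3)
    hsv = np.empty((n, 3))
    hsv[:, 0] = np.clip(h0 + rng.normal(0.0, 0.01, n), *_NERVE_H)
    hsv[:, 1] = np.clip(s0 + jitter_s, _SMUDGE_S[0] if smooth else _NERVE_S[0], 0.90)
    hsv[:, 2] = np.clip(v0 + jitter_v, _NERVE_V[0], _NERVE_V[1])
    return hsv


def paint_appearance(
    kind: str, target_area_px: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Paint one nerve of the given appearance class on a local canvas.

    Returns ``(mask, hsv)`` where ``mask`` is a tight boolean canvas and
    ``hsv`` holds per-painted-pixel HSV colours (row order ``mask.nonzero()``).
    ``single`` yields one connected component; the ``separated_*`` kinds yield
    2-6 components with inter-component gaps under 20 px so a single 20 x 20
    closing unifies them; ``smudge`` yields one smooth low-gradient blob. The
    painted area matches ``target_area_px`` within +-20%.
    """
    if kind not in APPEARANCE_KINDS:
        raise ValueError(f"unknown appearance kind {kind!r}")
    if target_area_px < 12:
        raise ValueError("target area too small to paint")

    if kind in ("single", "smudge"):
        aspect = rng.uniform(1.0, 3.0) if kind == "single" else rng.uniform(1.0, 1.8)
        angle = rng.uniform(0.0, np.pi)
        a = np.sqrt(target_area_px * aspect / np.pi)
        side = int(np.ceil(2 * a)) + 4
        mask = _blob_mask((side, side), side / 2, side / 2, target_area_px, aspect, angle)
    else:
        n_comp = int(rng.integers(2, 7)) if kind == "separated_small" else int(
            rng.integers(2, 5)
        )
        comp_area = max(target_area_px / n_comp, 6.0)
        comp_r = np.sqrt(comp_area / np.pi)
        comp_side = int(np.ceil(3.2 * comp_r)) + 6
        # Paint each component on its own canvas and trim to the painted
        # extent, then lay components out left to right with gaps of 4-14 px
        # between those extents and small vertical jitter: every gap stays
        # well under the 20 px reach of the closing, which bridges them.
        comps = []
        for _ in range(n_comp):
            canvas = np.zeros((comp_side, comp_side), dtype=bool)
            aspect = rng.uniform(1.0, 2.2)
            angle = rng.uniform(0.0, np.pi)
            if kind == "separated_clusters":
                # each component is a tight cluster of touching blobs; keep
                # adding small overlapping blobs until the component reaches
                # its area share (offsets small enough to stay connected)
                canvas |= _blob_mask(
                    canvas.shape, comp_side / 2, comp_side / 2,
                    comp_area * 0.6, aspect, angle,
                )
                while canvas.sum() < 0.88 * comp_area:
                    dy, dx = rng.uniform(-0.5, 0.5, 2) * comp_r
                    canvas |= _blob_mask(
                        canvas.shape, comp_side / 2 + dy, comp_side / 2 + dx,
                        comp_area * 0.3, aspect, angle,
                    )
            else:
                canvas |= _blob_mask(
                    canvas.shape, comp_side / 2, comp_side / 2, comp_area,
                    aspect, angle,
                )
            ys, xs = np.nonzero(canvas)
            comps.append(canvas[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1])
        gaps = rng.integers(4, 15, size=n_comp - 1)
        max_h = max(c.shape[0] for c in comps)
        height = max_h + 10
        width = sum(c.shape[1] for c in comps) + int(gaps.sum())
        mask = np.zeros((height, width), dtype=bool)
        x = 0
        for i, comp in enumerate(comps):
            # vertical centring with jitter small enough that neighbouring
            # components always overlap vertically
            y = (height - comp.shape[0]) // 2 + int(rng.integers(-3, 4))
            y = min(max(y, 0), height - comp.shape[0])
            mask[y : y + comp.shape[0], x : x + comp.shape[1]] |= comp
            x += comp.shape[1] + (int(gaps[i]) if i < n_comp - 1 else 0)

    base = _sample_nerve_hsv(rng, smudge=(kind == "smudge"))
    hsv = _textured_colour(mask, base, rng, smooth=(kind == "smudge"))
    return mask, hsv


def _paint_distractor(
    kind: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Paint one distractor blob; returns (mask, per-pixel HSV)."""
    if kind == "in_range_small":
        area = rng.uniform(20, 80)  # below the 100 px size criterion
        s_rng, v_rng, h_rng = (0.25, 0.5), (0.55, 0.9), (0.06, 0.18)
    elif kind == "in_range_diffuse":
        area = rng.uniform(200, 1200)  # survives the size filter
        s_rng, v_rng, h_rng = (0.22, 0.32), (0.78, 0.95), (0.06, 0.18)
    elif kind == "out_of_range":
        # weak non-specific uptake: brown-ish or yellowish but too pale for
        # the filter (saturation below its lower bound)
        area = rng.uniform(100, 900)
        if rng.random() < 0.5:
            s_rng, v_rng, h_rng = (0.06, 0.15), (0.72, 0.92), (0.08, 0.18)
        else:
            s_rng, v_rng, h_rng = (0.08, 0.18), (0.75, 0.95), (0.2, 0.3)
    else:
        raise ValueError(f"unknown distractor kind {kind!r}")
    aspect = rng.uniform(1.0, 2.5)
    a = np.sqrt(area * aspect / np.pi)
    side = int(np.ceil(2 * a)) + 4
    mask = _blob_mask(
        (side, side), side / 2, side / 2, area, aspect, rng.uniform(0, np.pi)
    )
    n = int(mask.sum())
    hsv = np.empty((n, 3))
    hsv[:, 0] = np.clip(rng.uniform(*h_rng) + rng.normal(0, 0.005, n), *h_rng)
    hsv[:, 1] = np.clip(rng.uniform(*s_rng) + rng.normal(0, 0.012, n), *s_rng)
    hsv[:, 2] = np.clip(rng.uniform(*v_rng) + rng.normal(0, 0.012, n), *v_rng)
    return mask, hsv


def _background_hsv(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Pale slide background with haematoxylin-like blue-purple ellipses."""
    h, w = shape
    hsv = np.empty((h, w, 3))
    hsv[:, :, 0] = rng.uniform(0.5, 0.9)
    hsv[:, :, 1] = np.clip(rng.normal(0.02, 0.008, (h, w)), 0.0, 0.06)
    hsv[:, :, 2] = np.clip(rng.normal(0.95, 0.012, (h, w)), 0.88, 1.0)
    n_nuclei = max(1, (h * w) // 6000)
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        area = rng.uniform(40, 250)
        m = _blob_mask(shape, cy, cx, area, rng.uniform(1.0, 2.0), rng.uniform(0, np.pi))
        k = int(m.sum())
        if k == 0:
            continue
        hsv[m, 0] = rng.uniform(0.65, 0.75)
        hsv[m, 1] = np.clip(rng.normal(rng.uniform(0.3, 0.55), 0.03, k), 0.2, 0.65)
        hsv[m, 2] = np.clip(rng.normal(rng.uniform(0.55, 0.8), 0.03, k), 0.45, 0.88)
    return hsv


def _place(
    occupied: list[Box],
    obj_h: int,
    obj_w: int,
    shape: tuple[int, int],
    rng: np.random.Generator,
    max_tries: int = 300,
) -> tuple[int, int]:
    """Find a top-left position whose padded box avoids all occupied boxes."""
    H, W = shape
    pad = _MIN_GAP_PX
    if obj_h > H - 2 * _BORDER_MARGIN or obj_w > W - 2 * _BORDER_MARGIN:
        raise ValueError(
            f"object of size {obj_h}x{obj_w} exceeds the image capacity {H}x{W}"
        )
    for _ in range(max_tries):
        y = int(rng.integers(_BORDER_MARGIN, H - obj_h - _BORDER_MARGIN + 1))
        x = int(rng.integers(_BORDER_MARGIN, W - obj_w - _BORDER_MARGIN + 1))
        cand = Box(max(x - pad, 0), max(y - pad, 0),
                   min(obj_w + 2 * pad, W - max(x - pad, 0)),
                   min(obj_h + 2 * pad, H - max(y - pad, 0)))
        if not any(cand.intersects(b) for b in occupied):
            occupied.append(Box(x, y, obj_w, obj_h))
            return y, x
    raise ValueError(
        "could not place all requested objects; the image capacity is exceeded"
    )


def generate_slide(spec: SyntheticSpec) -> SyntheticSlide:
    """Generate one synthetic slide from its spec; deterministic per spec.

    Raises ``ValueError`` when a requested nerve cannot fit in the image.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_height_px, spec.image_width_px)
    hsv = _background_hsv(shape, rng)
    truth = np.zeros(shape, dtype=bool)
    occupied: list[Box] = []

    # -- nerves ------------------------------------------------------------
    kinds = list(spec.appearance_mix)
    probs = np.array([spec.appearance_mix[k] for k in kinds], dtype=float)
    lo_px = spec.nerve_area_range_um2[0] / spec.microns_per_pixel**2
    hi_px = spec.nerve_area_range_um2[1] / spec.microns_per_pixel**2
    nerve_boxes: list[Box] = []
    nerve_kinds: list[str] = []
    nerve_areas: list[int] = []
    for _ in range(spec.n_nerves):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        target = float(np.exp(rng.uniform(np.log(lo_px), np.log(hi_px))))
        mask, colours = paint_appearance(kind, max(int(round(target)), 12), rng)
        y, x = _place(occupied, mask.shape[0], mask.shape[1], shape, rng)
        ys, xs = np.nonzero(mask)
        hsv[ys + y, xs + x] = colours
        truth[ys + y, xs + x] = True
        nerve_boxes.append(Box(x, y, mask.shape[1], mask.shape[0]))
        nerve_kinds.append(kind)
        nerve_areas.append(int(mask.sum()))

    # -- distractors -------------------------------------------------------
    distractor_boxes: list[Box] = []
    distractor_kinds: list[str] = []
    # half in filter range (mostly diffuse washes that survive the size rule,
    # some below it), half brown-ish but outside the range
    _cycle = ("in_range_diffuse", "out_of_range", "in_range_small",
              "out_of_range", "in_range_diffuse", "out_of_range")
    for i in range(spec.n_distractors):
        kind = _cycle[i % len(_cycle)]
        mask, colours = _paint_distractor(kind, rng)
        y, x = _place(occupied, mask.shape[0], mask.shape[1], shape, rng)
        ys, xs = np.nonzero(mask)
        hsv[ys + y, xs + x] = colours
        distractor_boxes.append(Box(x, y, mask.shape[1], mask.shape[0]))
        distractor_kinds.append(kind)

    image = SlideImage(
        pixels=(hsv2rgb(hsv) * 255.0).round().astype(np.uint8),
        microns_per_pixel=spec.microns_per_pixel,
        slide_id=f"synthetic-{spec.seed}",
    )

    # -- annotations -------------------------------------------------------
    pad = 3
    complete = AnnotationSet(
        [
            Annotation(
                Box(
                    max(b.x0 - pad, 0),
                    max(b.y0 - pad, 0),
                    min(b.width + 2 * pad, spec.image_width_px - max(b.x0 - pad, 0)),
                    min(b.height + 2 * pad, spec.image_height_px - max(b.y0 - pad, 0)),
                )
            )
            for b in nerve_boxes
        ],
        image.slide_id,
    )
    n_expert = int(round(spec.annotation_completeness * spec.n_nerves))
    expert_idx = sorted(rng.choice(spec.n_nerves, size=n_expert, replace=False)) if (
        spec.n_nerves
    ) else []
    expert = complete.subset(expert_idx)

    # -- negative regions: around distractors, plus one blank box ----------
    negatives: list[Box] = []
    for b in distractor_boxes:
        x0, y0 = max(b.x0 - 10, 0), max(b.y0 - 10, 0)
        region = Box(
            x0, y0,
            min(b.width + 20, spec.image_width_px - x0),
            min(b.height + 20, spec.image_height_px - y0),
        )
        if not truth[region.slices()].any():
            negatives.append(region)
    for _ in range(50):  # one guaranteed nerve-free blank region, if space allows
        side = 64
        y = int(rng.integers(0, spec.image_height_px - side + 1))
        x = int(rng.integers(0, spec.image_width_px - side + 1))
        region = Box(x, y, side, side)
        # keep clear of nerves by more than the closing reach, so no
        # closing-grown nerve ROI can ever intersect this region
        clearance = Box(
            max(x - 24, 0), max(y - 24, 0),
            min(side + 48, spec.image_width_px - max(x - 24, 0)),
            min(side + 48, spec.image_height_px - max(y - 24, 0)),
        )
        if not truth[clearance.slices()].any():
            negatives.append(region)
            break

    slide = SyntheticSlide(
        image=image,
        truth_mask=truth,
        complete_annotations=complete,
        expert_annotations=expert,
        negative_regions=negatives,
        nerve_kinds=nerve_kinds,
        nerve_areas_px=nerve_areas,
        distractor_boxes=distractor_boxes,
        distractor_kinds=distractor_kinds,
    )
    _check_invariants(slide)
    return slide


def _check_invariants(slide: SyntheticSlide) -> None:
    """Construction-time checks of the generator's contracts."""
    assert len(slide.expert_annotations) <= len(slide.complete_annotations)
    for region in slide.negative_regions:
        assert not slide.truth_mask[region.slices()].any()
    rng_default = ColorFilterRange()
    if slide.truth_mask.any():
        from .color_filter import rgb_to_hsv_normalised

        hsv = rgb_to_hsv_normalised(slide.image)
        inside = rng_default.contains(hsv[slide.truth_mask])
        # uint8 quantisation can nudge isolated pixels; colours are sampled
        # with enough margin that effectively all nerve pixels stay in range
        assert inside.mean() > 0.99, "nerve colours fell outside the filter range"
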