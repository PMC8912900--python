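"""HSV colour thresholding for DAB (brown) stain detection.

Nerves stained with PGP9.5 render brown; the haematoxylin counterstain renders
blue-purple. A fixed range filter in normalised HSV space separates the two:
the default range is ``(0.04, 0.2, 0.4)`` to ``(0.2, 1, 1)``, i.e. brown hues
with at least moderate saturation and value. Bounds are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .types import SlideImage

__all__ = ["ColorFilterRange", "rgb_to_hsv_normalised", "apply_color_filter"]


@dataclass(frozen=True)
class ColorFilterRange:
    """Inclusive componentwise HSV range with all channels in [0, 1].

    Hue wrap-around is not supported: ``lower`` must be <= ``upper`` in every
    component (the default brown range never crosses hue 0).
    """

    lower: tuple[float, float, float] = (0.04, 0.2, 0.4)
    upper: tuple[float, float, float] = (0.2, 1.0, 1.0)

    def __post_init__(self) -> None:
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (3,) or up.shape != (3,):
            raise ValueError("lower and upper must be (h, s, v) triples")
        if np.any(lo < 0) or np.any(up > 1):
            raise ValueError("HSV bounds must lie in [0, 1]")
        if np.any(lo > up):
            raise ValueError(
                "lower must be <= upper componentwise (hue wrap-around is not "
                f"supported): {self.lower} vs {self.upper}"
            )

    def contains(self, hsv: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside the range, bounds inclusive."""
        hsv = np.asarray(hsv, dtype=float)
        if hsv.shape[-1] != 3:
            raise ValueError(f"expected trailing HSV axis of size 3, got {hsv.shape}")
        lo = np.asarray(self.lower)
        up = np.asarray(self.upper)
        return np.all((hsv >= lo) & (hsv <= up), axis=-1)


def rgb_to_hsv_normalised(image: SlideImage | np.ndarray) -> np.ndarray:
    """Convert an RGB raster to HSV with every channel normalised to [0, 1].

    Accepts uint8 rasters in [0, 255] or float rasters in [0, 1]; the scale is
    inferred from the dtype. Hue is normalised to [0, 1) (1.0 == 360 degrees).
    """
    rgb = image.pixels if isinstance(image, SlideImage) else np.asarray(image)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB raster, got shape {rgb.shape}")
    if np.issubdtype(rgb.dtype, np.integer):
        rgb = rgb.astype(np.float64) / 255.0
    else:
        rgb = rgb.astype(np.float64)
        if rgb.max() > 1.0 + 1e-9:
            raise ValueError("float RGB input must be scaled to [0, 1]")
    return rgb2hsv(rgb)


def apply_color_filter(
    hsv: np.ndarray, range_: ColorFilterRange | None = None
) -> np.ndarray:
    """Threshold an HSV raster to a boolean brown-stain mask.

    A pixel is True iff ``lower <= (h, s, v) <= upper`` componentwise.
    """
    if range_ is None:
        range_ = ColorFilterRange()
    return range_.contains(hsv)
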