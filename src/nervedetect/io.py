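"""File formats: images (TIFF/PNG), annotations (GeoJSON/CSV), masks, reports.

Annotations travel either as GeoJSON FeatureCollections of rectangular
polygons carrying a ``class`` property (the shape QuPath exports) or as flat
CSV with columns ``slide_id,x,y,width,height,label``. Box round-trips are
lossless in both formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import SyntheticSpec
from .types import Annotation, AnnotationSet, Box, DetectionResult, SlideImage

__all__ = [
    "read_slide",
    "write_slide",
    "read_mask",
    "write_mask",
    "read_annotations",
    "write_annotations",
    "write_detections",
    "read_boxes_csv",
    "write_boxes_csv",
    "load_synthetic_spec",
]

_CSV_COLUMNS = ["slide_id", "x", "y", "width", "height", "label"]


def read_slide(path: str | Path, microns_per_pixel: float = 0.5) -> SlideImage:
    """Read an RGB TIFF/PNG raster as a SlideImage."""
    path = Path(path)
    px = (tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff")
          else iio.imread(path))
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {px.shape}")
    return SlideImage(px.astype(np.uint8), microns_per_pixel, slide_id=path.stem)


def write_slide(image: SlideImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as 8-bit single-channel 0/255."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    arr = (tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff")
           else iio.imread(path))
    return np.asarray(arr) > 0


def _box_to_polygon(box: Box) -> list[list[list[float]]]:
    x0, y0, x1, y1 = box.x0, box.y0, box.x1, box.y1
    return [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]]


def _polygon_to_box(coords, index: int) -> Box:
    try:
        ring = np.asarray(coords[0], dtype=float)
        xs, ys = ring[:, 0], ring[:, 1]
        x0, y0 = int(np.floor(xs.min())), int(np.floor(ys.min()))
        x1, y1 = int(np.ceil(xs.max())), int(np.ceil(ys.max()))
        return Box(x0, y0, x1 - x0, y1 - y0)
    except (IndexError, ValueError, TypeError) as exc:
        raise ValueError(f"feature {index}: invalid polygon geometry: {exc}") from exc


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Write as GeoJSON (``.geojson``/``.json``) or CSV (``.csv``)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        write_boxes_csv(annotations, path)
        return
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Polygon",
                         "coordinates": _box_to_polygon(a.box)},
            "properties": {"class": a.label},
        }
        for a in annotations
    ]
    payload = {"type": "FeatureCollection", "features": features,
               "properties": {"slide_id": annotations.slide_id}}
    path.write_text(json.dumps(payload, indent=1))


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection or CSV into an AnnotationSet.

    Non-polygon geometries and malformed rows are rejected with the feature
    or line index in the message.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_boxes_csv(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON: {exc}") from exc
    if payload.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    annotations = []
    for i, feat in enumerate(payload.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValueError(
                f"feature {i}: only Polygon geometries are supported, "
                f"got {geom.get('type')!r}"
            )
        box = _polygon_to_box(geom.get("coordinates"), i)
        label = (feat.get("properties") or {}).get("class", "nerve")
        annotations.append(Annotation(box, label))
    slide_id = (payload.get("properties") or {}).get("slide_id", path.stem)
    return AnnotationSet(annotations, slide_id)


def write_boxes_csv(annotations: AnnotationSet, path: str | Path) -> None:
    rows = [
        {"slide_id": annotations.slide_id, "x": a.box.x0, "y": a.box.y0,
         "width": a.box.width, "height": a.box.height, "label": a.label}
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_boxes_csv(path: str | Path) -> AnnotationSet:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    annotations = []
    for i, row in df.iterrows():
        try:
            box = Box(int(row.x), int(row.y), int(row.width), int(row.height))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        annotations.append(Annotation(box, str(row.label)))
    slide_id = str(df.slide_id.iloc[0]) if len(df) else Path(path).stem
    return AnnotationSet(annotations, slide_id)


def write_detections(result: DetectionResult, path: str | Path) -> None:
    """Write final prediction boxes in the same formats as annotations."""
    anns = AnnotationSet(
        [Annotation(b, "detection") for b in result.boxes], result.slide_id
    )
    write_annotations(anns, path)


def load_synthetic_spec(path: str | Path) -> SyntheticSpec:
    """Read a SyntheticSpec from a YAML/JSON config file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if "appearance_mix" in raw:
        raw["appearance_mix"] = dict(raw["appearance_mix"])
    for key in ("nerve_area_range_um2",):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return SyntheticSpec(**raw)
    except TypeError as exc:
        raise ValueError(f"{path}: invalid spec keys: {exc}") from exc
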