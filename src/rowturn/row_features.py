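"""ROI-strip centroid features along segmented crop rows.

Full-width horizontal strips (default 40 px tall, laid out every 60 px) are
intersected with each filled row contour; each connected piece of the
intersection that survives an area screen contributes its center of mass as
one centerline feature point.  Centroids are grouped by contour for the
downstream per-row line fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidGeometryError, InvalidInputError
from .row_segmentation import BinaryMask, Contour, ContourSet

__all__ = [
    "RoiStrip",
    "IntersectionRegion",
    "FeaturePoint",
    "build_strips",
    "intersect",
    "screen_regions",
    "centroid",
    "extract_feature_points",
    "features_to_frame",
    "feature_overlay",
]

DEFAULT_STRIP_HEIGHT = 40
DEFAULT_STRIP_INTERVAL = 60
DEFAULT_REGION_MIN_AREA = 50.0


@dataclass(frozen=True)
class RoiStrip:
    """Full-width horizontal band [y_top, y_top + height)."""

    y_top: int
    height: int
    width: int
    index: int


@dataclass(eq=False)
class IntersectionRegion:
    """One connected component of strip AND filled contour."""

    contour_id: int
    strip_index: int
    pixels: np.ndarray  # (N, 2) array of (row, col) indices
    area: int


@dataclass(frozen=True)
class FeaturePoint:
    """Sub-pixel center of mass of one intersection region."""

    Cx: float
    Cy: float
    contour_id: int
    strip_index: int
    area: int


def build_strips(
    image_height: int,
    image_width: int,
    strip_height: int = DEFAULT_STRIP_HEIGHT,
    interval: int = DEFAULT_STRIP_INTERVAL,
) -> list[RoiStrip]:
    """Strips at y_top = 0, interval, 2*interval, ... fully inside the image."""
    if strip_height > image_height:
        raise InvalidGeometryError(
            f"strip height {strip_height} exceeds image height {image_height}"
        )
    if interval <= 0:
        raise InvalidGeometryError("strip interval must be positive")
    strips = []
    y = 0
    idx = 0
    while y + strip_height <= image_height:
        strips.append(RoiStrip(y_top=y, height=strip_height, width=image_width, index=idx))
        y += interval
        idx += 1
    return strips


def intersect(strip: RoiStrip, contour: Contour) -> list[IntersectionRegion]:
    """Connected components of the bitwise AND of strip band and filled contour."""
    filled = contour.filled
    if filled.shape[1] != strip.width:
        raise InvalidInputError("strip and contour mask widths differ")
    band = filled[strip.y_top : strip.y_top + strip.height, :]
    labeled, n = ndimage.label(band, structure=np.ones((3, 3), dtype=int))
    regions = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labeled == lab)
        pixels = np.column_stack([rr + strip.y_top, cc])
        regions.append(
            IntersectionRegion(
                contour_id=contour.contour_id,
                strip_index=strip.index,
                pixels=pixels,
                area=int(pixels.shape[0]),
            )
        )
    return regions


def screen_regions(
    regions: list[IntersectionRegion], min_area: float = DEFAULT_REGION_MIN_AREA
) -> list[IntersectionRegion]:
    """Drop regions with area < min_area, preserving order (idempotent)."""
    if min_area < 0:
        raise InvalidInputError("min_area must be >= 0")
    return [r for r in regions if r.area >= min_area]


def centroid(region: IntersectionRegion) -> FeaturePoint:
    """Center of mass Cx = mean x, Cy = mean y over the region's pixels."""
    if region.area == 0:
        raise InvalidInputError("cannot take the centroid of an empty region")
    cy = float(region.pixels[:, 0].mean())
    cx = float(region.pixels[:, 1].mean())
    return FeaturePoint(
        Cx=cx,
        Cy=cy,
        contour_id=region.contour_id,
        strip_index=region.strip_index,
        area=region.area,
    )


def extract_feature_points(
    contours: ContourSet,
    image_height: int,
    image_width: int,
    strip_height: int = DEFAULT_STRIP_HEIGHT,
    interval: int = DEFAULT_STRIP_INTERVAL,
    min_region_area: float = DEFAULT_REGION_MIN_AREA,
) -> dict[int, list[FeaturePoint]]:
    """Full strip/intersect/screen/centroid chain, grouped by contour id."""
    strips = build_strips(image_height, image_width, strip_height, interval)
    grouped: dict[int, list[FeaturePoint]] = {c.contour_id: [] for c in contours}
    for c in contours:
        for strip in strips:
            regions = screen_regions(intersect(strip, c), min_region_area)
            grouped[c.contour_id].extend(centroid(r) for r in regions)
    return grouped


def features_to_frame(grouped: dict[int, list[FeaturePoint]]) -> pd.DataFrame:
    rows = [
        {
            "contour_id": fp.contour_id,
            "strip_index": fp.strip_index,
            "Cx": fp.Cx,
            "Cy": fp.Cy,
            "area": fp.area,
        }
        for pts in grouped.values()
        for fp in pts
    ]
    return pd.DataFrame(rows, columns=["contour_id", "strip_index", "Cx", "Cy", "area"])


def feature_overlay(
    image: np.ndarray,
    contours: ContourSet,
    grouped: dict[int, list[FeaturePoint]],
    strip_height: int = DEFAULT_STRIP_HEIGHT,
    interval: int = DEFAULT_STRIP_INTERVAL,
) -> np.ndarray:
    """Debug rendering: blue strips, red intersections, orange centroids."""
    from skimage.draw import disk

    out = np.asarray(image, dtype=np.uint8).copy()
    h, w = out.shape[:2]
    strips = build_strips(h, w, strip_height, interval)
    for strip in strips:
        band = out[strip.y_top : strip.y_top + strip.height, :]
        band[:] = (0.7 * band + 0.3 * np.array([60, 60, 220])).astype(np.uint8)
    for c in contours:
        for strip in strips:
            band = c.filled[strip.y_top : strip.y_top + strip.height, :]
            rr, cc = np.nonzero(band)
            out[rr + strip.y_top, cc] = [220, 40, 40]
    for pts in grouped.values():
        for fp in pts:
            rr, cc = disk((fp.Cy, fp.Cx), 3, shape=(h, w))
            out[rr, cc] = [255, 160, 0]
    return out
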