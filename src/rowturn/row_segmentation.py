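"""Crop-row segmentation: HSV green thresholding, staged opening, contours.

Green vegetation is separated from soil, straw and shadow by thresholding
hue/saturation/value; the binary mask is then cleaned by a staged opening
schedule in which pass ``i`` erodes with a (6-i, 6-i) rectangle and dilates
with an (i, i) rectangle, for i in {1, 3, 5}.  Early passes erode hard to
kill speckle; later passes dilate hard to reconnect fragmented rows.
External contours of the surviving connected components are kept when their
filled area clears a minimum-area threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color, measure

from .errors import InvalidInputError, InvalidScheduleError

__all__ = [
    "HsvThresholds",
    "MorphologySchedule",
    "BinaryMask",
    "Contour",
    "ContourSet",
    "green_mask",
    "open_schedule",
    "extract_contours",
    "default_min_area",
]

#: Reference image size for the min-area default.
_REF_PIXELS = 640 * 480
_DEFAULT_MIN_AREA = 500.0


@dataclass(frozen=True)
class HsvThresholds:
    """Inclusive HSV band for "green": hue in degrees, S and V in [0, 1]."""

    h_min: float = 70.0
    h_max: float = 170.0
    s_min: float = 0.25
    s_max: float = 1.0
    v_min: float = 0.20
    v_max: float = 1.0

    def __post_init__(self) -> None:
        if not (self.h_min < self.h_max and self.s_min < self.s_max
                and self.v_min < self.v_max):
            raise ValueError("HSV bounds must satisfy min < max per channel")


@dataclass(frozen=True)
class MorphologySchedule:
    """Staged opening: pass i erodes with (6-i, 6-i) then dilates with (i, i)."""

    iterations: tuple[int, ...] = (1, 3, 5)

    def erosion_kernel(self, i: int) -> tuple[int, int]:
        return (6 - i, 6 - i)

    def dilation_kernel(self, i: int) -> tuple[int, int]:
        return (i, i)

    def validate(self) -> None:
        for i in self.iterations:
            for k in (*self.erosion_kernel(i), *self.dilation_kernel(i)):
                if k < 1:
                    raise InvalidScheduleError(
                        f"iteration {i} produces a kernel dimension {k} < 1"
                    )


class BinaryMask:
    """Strictly binary image mask backed by a boolean array."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values)
        if values.ndim != 2:
            raise InvalidInputError("mask must be 2-D")
        self.values = values.astype(bool)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_uint8(self) -> np.ndarray:
        """0/255 representation for PNG export."""
        return (self.values * np.uint8(255))


@dataclass(eq=False)
class Contour:
    """One retained crop-row contour: closed polygon, area, filled mask."""

    contour_id: int
    polygon: np.ndarray  # (N, 2) array of (x, y) vertices, closed
    area: float  # filled-region area in pixels^2
    filled: np.ndarray  # full-size boolean mask of the filled region


@dataclass
class ContourSet:
    contours: list[Contour] = field(default_factory=list)
    min_area: float = _DEFAULT_MIN_AREA

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self):
        return iter(self.contours)


def default_min_area(width: int, height: int) -> float:
    """Contour area threshold, 500 px^2 at 640x480 scaled by image area."""
    return _DEFAULT_MIN_AREA * (width * height) / _REF_PIXELS


def green_mask(image: np.ndarray, th: HsvThresholds | None = None) -> BinaryMask:
    """Threshold an RGB image to the configured HSV green band.

    ``image`` may be uint8 [0, 255] or float [0, 1]; hue is handled in
    degrees [0, 360).
    """
    if th is None:
        th = HsvThresholds()
    image = np.asarray(image)
    if image.size == 0 or image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError("expected a non-empty HxWx3 RGB image")
    hsv = color.rgb2hsv(image)  # H, S, V all in [0, 1]
    h = hsv[..., 0] * 360.0
    s = hsv[..., 1]
    v = hsv[..., 2]
    inside = (
        (h >= th.h_min) & (h <= th.h_max)
        & (s >= th.s_min) & (s <= th.s_max)
        & (v >= th.v_min) & (v <= th.v_max)
    )
    return BinaryMask(inside)


def open_schedule(mask: BinaryMask, sched: MorphologySchedule | None = None) -> BinaryMask:
    """Apply the staged opening schedule to a binary mask.

    Structuring elements are filled rectangles; pixels outside the image are
    treated as background for both erosion and dilation.  A kernel of size
    (1, 1) is the identity.
    """
    if sched is None:
        sched = MorphologySchedule()
    sched.validate()
    out = mask.values
    for i in sched.iterations:
        ek = sched.erosion_kernel(i)
        dk = sched.dilation_kernel(i)
        if ek != (1, 1):
            out = ndimage.binary_erosion(out, structure=np.ones(ek), border_value=0)
        if dk != (1, 1):
            out = ndimage.binary_dilation(out, structure=np.ones(dk), border_value=0)
    return BinaryMask(out)


def extract_contours(mask: BinaryMask, min_area: float | None = None) -> ContourSet:
    """External contours of 8-connected components with area >= ``min_area``.

    Components are filled (holes included in the region) before the area
    test, mirroring a filled-contour interpretation of the row outline.
    """
    if min_area is None:
        min_area = default_min_area(mask.width, mask.height)
    if min_area < 0:
        raise InvalidInputError("min_area must be >= 0")
    labeled, n = ndimage.label(mask.values, structure=np.ones((3, 3), dtype=int))
    contours: list[Contour] = []
    next_id = 0
    for lab in range(1, n + 1):
        region = labeled == lab
        filled = ndimage.binary_fill_holes(region)
        area = float(filled.sum())
        if area < min_area:
            continue
        # Trace the external boundary on a padded copy so edge-touching
        # components still yield a closed curve.
        padded = np.pad(filled, 1).astype(float)
        traces = measure.find_contours(padded, 0.5)
        if not traces:
            continue
        trace = max(traces, key=len)  # outer boundary is the longest
        polygon = np.column_stack([trace[:, 1] - 1.0, trace[:, 0] - 1.0])  # (x, y)
        contours.append(Contour(next_id, polygon, area, filled))
        next_id += 1
    return ContourSet(contours, min_area=min_area)
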