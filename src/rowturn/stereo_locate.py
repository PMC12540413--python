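"""Stereo disparity-to-depth conversion and 3D localization of detections.

Depth follows the triangulation relation Zc = f*B/d with focal length f
(pixels) and baseline B (meters); a pixel is then lifted into the camera
frame via Xc = (u-cx)*Zc/fx, Yc = (v-cy)*Zc/fy and into the world frame by
the rigid transform of :mod:`rowturn.camera_geometry`.

A detection's bounding box is reduced to one 3D point by taking the bbox
center as the pixel and the median of the valid disparities inside the
central 50% x 50% sub-box as the disparity — robust when the box edges
straddle background.  Error metrics (per-axis absolute differences,
Euclidean norm, relative error in percent of the true range) are computed at
full precision; rounding happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .camera_geometry import (
    CameraPoint,
    CameraPose,
    Intrinsics,
    PixelPoint,
    WorldPoint,
    camera_to_world,
)
from .errors import (
    InvalidDisparityError,
    InvalidInputError,
    UndefinedRelativeErrorError,
    UnlocalizableDetectionError,
)

__all__ = [
    "StereoParams",
    "DisparityMap",
    "Detection",
    "Localization3D",
    "LocalizationError",
    "depth_from_disparity",
    "pixel_to_camera_3d",
    "locate_detection",
    "localization_error",
    "error_table",
    "load_detections",
]


@dataclass(frozen=True)
class StereoParams:
    """Stereo rig: focal length ``f`` in pixels, baseline ``B`` in meters."""

    f: float
    B: float

    def __post_init__(self) -> None:
        if not (self.f > 0 and self.B > 0):
            raise ValueError("stereo focal length and baseline must be positive")


@dataclass
class DisparityMap:
    """Dense per-pixel disparity in pixels; values <= 0 are invalid.

    When ``is_depth`` is True the values are meters and bypass the
    disparity-to-depth conversion.
    """

    values: np.ndarray
    is_depth: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidInputError("disparity map must be 2-D")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def valid(self) -> np.ndarray:
        return self.values > 0

    @classmethod
    def load(cls, path: str | Path, is_depth: bool = False) -> "DisparityMap":
        """Read a single-channel float image (.tif/.tiff) or .npy array."""
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            values = tifffile.imread(str(path))
        elif path.suffix.lower() == ".npy":
            values = np.load(path)
        else:
            raise InvalidInputError(f"unsupported disparity format: {path.suffix}")
        return cls(np.asarray(values, dtype=np.float64), is_depth=is_depth)

    def save(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.values.astype(np.float32))


@dataclass(frozen=True)
class Detection:
    """Axis-aligned detection box (u_min, v_min, u_max, v_max) in pixels."""

    bbox: tuple[float, float, float, float]
    label: str = "headland"
    score: float = 1.0

    def __post_init__(self) -> None:
        u0, v0, u1, v1 = self.bbox
        if not (u0 < u1 and v0 < v1):
            raise ValueError(f"degenerate bbox {self.bbox}")

    @property
    def center(self) -> tuple[float, float]:
        u0, v0, u1, v1 = self.bbox
        return (0.5 * (u0 + u1), 0.5 * (v0 + v1))


@dataclass(frozen=True)
class Localization3D:
    camera_point: CameraPoint
    world_point: WorldPoint
    source_pixel: PixelPoint
    depth_Zc: float


@dataclass(frozen=True)
class LocalizationError:
    """Per-axis absolute errors (m), their Euclidean norm, and relative %."""

    dX: float
    dY: float
    dZ: float
    euclidean: float
    relative: float


def depth_from_disparity(d: float, s: StereoParams) -> float:
    """Depth Zc = f*B/d in meters; raises on non-positive disparity."""
    if not d > 0:
        raise InvalidDisparityError(f"disparity must be positive, got {d}")
    return s.f * s.B / d


def pixel_to_camera_3d(p: PixelPoint, Zc: float, K: Intrinsics) -> CameraPoint:
    """Lift a pixel at known depth into the camera frame."""
    if not Zc > 0:
        raise InvalidDisparityError(f"depth must be positive, got {Zc}")
    Xc = (p.u - K.cx) * Zc / K.fx
    Yc = (p.v - K.cy) * Zc / K.fy
    return CameraPoint(Xc, Yc, Zc)


def _core_slices(det: Detection, shape: tuple[int, int]) -> tuple[slice, slice]:
    """Central 50% x 50% sub-box around the integer bbox center.

    The sub-box has odd extents symmetric about the center pixel, so the
    median of a disparity field that varies only along rows reduces exactly
    to the center pixel's value.
    """
    u0, v0, u1, v1 = det.bbox
    uc = int(round(0.5 * (u0 + u1)))
    vc = int(round(0.5 * (v0 + v1)))
    hw = max(0, int((u1 - u0) // 4))
    hh = max(0, int((v1 - v0) // 4))
    h, w = shape
    uc = min(max(uc, 0), w - 1)
    vc = min(max(vc, 0), h - 1)
    return (
        slice(max(vc - hh, 0), min(vc + hh + 1, h)),
        slice(max(uc - hw, 0), min(uc + hw + 1, w)),
    )


def locate_detection(
    det: Detection,
    disp: DisparityMap,
    s: StereoParams,
    K: Intrinsics,
    pose: CameraPose,
) -> Localization3D:
    """Lift a detection to a single 3D point in camera and world frames.

    The source pixel is the bbox center; the depth comes from the median of
    the valid disparities (or depths) inside the central 50% sub-box.
    """
    rows, cols = _core_slices(det, disp.values.shape)
    core = disp.values[rows, cols]
    valid = core[core > 0]
    if valid.size == 0:
        raise UnlocalizableDetectionError(
            f"no valid disparity in the core of bbox {det.bbox}"
        )
    med = float(np.median(valid))
    depth = med if disp.is_depth else depth_from_disparity(med, s)
    uc, vc = det.center
    pixel = PixelPoint(uc, vc)
    camera_point = pixel_to_camera_3d(pixel, depth, K)
    world_point = camera_to_world(camera_point, pose)
    return Localization3D(camera_point, world_point, pixel, depth)


def localization_error(measured, actual) -> LocalizationError:
    """Per-axis, Euclidean, and relative (percent) localization errors.

    Everything is computed at full precision; the relative error divides the
    Euclidean error by the norm of the true coordinates.
    """
    measured = np.asarray(measured, dtype=float)
    actual = np.asarray(actual, dtype=float)
    norm = float(np.linalg.norm(actual))
    if norm == 0.0:
        raise UndefinedRelativeErrorError("actual position is the origin")
    diff = np.abs(measured - actual)
    euclid = float(np.linalg.norm(diff))
    return LocalizationError(
        dX=float(diff[0]),
        dY=float(diff[1]),
        dZ=float(diff[2]),
        euclidean=euclid,
        relative=100.0 * euclid / norm,
    )


def error_table(pairs: list[tuple]) -> pd.DataFrame:
    """Tabulate localization errors for (true, measured) coordinate pairs."""
    rows = []
    for i, (actual, measured) in enumerate(pairs, start=1):
        err = localization_error(measured, actual)
        rows.append(
            {
                "number": i,
                "true_x": actual[0],
                "true_y": actual[1],
                "true_z": actual[2],
                "meas_x": measured[0],
                "meas_y": measured[1],
                "meas_z": measured[2],
                "dX": err.dX,
                "dY": err.dY,
                "dZ": err.dZ,
                "euclidean": err.euclidean,
                "relative_pct": err.relative,
            }
        )
    return pd.DataFrame(rows)


def load_detections(path: str | Path) -> list[Detection]:
    """Read detections from a JSON list of {label, score, bbox}."""
    import json

    with open(path) as fh:
        raw = json.load(fh)
    return [
        Detection(bbox=tuple(d["bbox"]), label=d.get("label", "headland"),
                  score=float(d.get("score", 1.0)))
        for d in raw
    ]
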