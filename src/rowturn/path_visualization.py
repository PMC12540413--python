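"""Projection of planned world-frame paths into the image and overlay drawing.

Each waypoint is transformed into the camera frame; points behind the image
plane (Zc <= 0) are dropped and counted, the rest are projected through the
pinhole model with distortion correction and clamped to the image boundary
(clamps are counted too).  Retained points are rendered as filled discs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera_geometry import (
    CameraPose,
    DistortionModel,
    Intrinsics,
    PixelPoint,
    clamp_to_image,
    project_points,
    transform_points_to_camera,
)
from .errors import InvalidInputError, PathNotVisibleError

__all__ = ["ProjectedPath", "project_path", "draw_path"]


@dataclass
class ProjectedPath:
    points: list[PixelPoint] = field(default_factory=list)
    dropped_count: int = 0  # waypoints behind the camera
    clamped_count: int = 0  # waypoints moved onto the border


def project_path(
    path,
    pose: CameraPose,
    K: Intrinsics,
    dist: DistortionModel | None = None,
) -> ProjectedPath:
    """Project a planned path (or raw (N, 3) world array) into the image."""
    waypoints = getattr(path, "waypoints", path)
    waypoints = np.atleast_2d(np.asarray(waypoints, dtype=float))
    if waypoints.size == 0:
        raise InvalidInputError("empty path")
    cam = transform_points_to_camera(waypoints, pose)
    visible = cam[:, 2] > 0
    dropped = int((~visible).sum())
    if not visible.any():
        raise PathNotVisibleError("every waypoint lies behind the camera")
    pix = project_points(cam[visible], K, dist)
    points = []
    clamped = 0
    for u, v in pix:
        p = clamp_to_image(PixelPoint(float(u), float(v)), K)
        if not p.in_bounds:
            clamped += 1
        points.append(p)
    return ProjectedPath(points=points, dropped_count=dropped, clamped_count=clamped)


def draw_path(
    image: np.ndarray,
    proj: ProjectedPath,
    radius: int = 3,
    color: tuple[int, int, int] = (0, 255, 0),
) -> np.ndarray:
    """Return a copy of ``image`` with a filled disc at each retained point."""
    from skimage.draw import disk

    out = np.asarray(image, dtype=np.uint8).copy()
    h, w = out.shape[:2]
    for p in proj.points:
        rr, cc = disk((round(p.v), round(p.u)), radius, shape=(h, w))
        out[rr, cc] = color
    return out
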