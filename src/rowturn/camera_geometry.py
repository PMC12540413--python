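"""Camera frames, world<->camera rigid transform, and pinhole projection.

The world frame is ground-anchored: Z_W points along the vehicle's forward
direction, Y_W is height above the ground plane, and X_W is lateral (negative
to the right of the Z_W axis, positive to the left).  The camera frame is
obtained by rotating the world frame about X_W by the pitch angle ``gamma``
and translating its origin to ``T`` (default 2 m above the ground).  Pixels
use the top-left origin, u rightward, v downward, with continuous sub-pixel
coordinates; rounding happens only at draw time.

Angles are degrees at every API boundary and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PointBehindCameraError

__all__ = [
    "Intrinsics",
    "DistortionModel",
    "CameraPose",
    "PixelPoint",
    "CameraPoint",
    "WorldPoint",
    "rotation_about_x",
    "camera_to_world",
    "world_to_camera",
    "transform_points_to_world",
    "transform_points_to_camera",
    "project_to_pixel",
    "project_points",
    "clamp_to_image",
]


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics in pixel units."""

    fx: float
    fy: float
    cx: float
    cy: float
    image_width: int = 640
    image_height: int = 480

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.image_width):
            raise ValueError("cx outside the image")
        if not (0 <= self.cy < self.image_height):
            raise ValueError("cy outside the image")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 intrinsic matrix K."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class DistortionModel:
    """Radial-tangential lens distortion (k1, k2, k3 radial; p1, p2 tangential).

    The all-zero model is the identity; coefficients are dimensionless and
    applied to normalized image coordinates.
    """

    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    k3: float = 0.0

    def __post_init__(self) -> None:
        coeffs = (self.k1, self.k2, self.p1, self.p2, self.k3)
        if not all(np.isfinite(c) for c in coeffs):
            raise ValueError("distortion coefficients must be finite")

    @property
    def is_identity(self) -> bool:
        return self.k1 == self.k2 == self.p1 == self.p2 == self.k3 == 0.0

    @classmethod
    def from_list(cls, coeffs) -> "DistortionModel":
        """Build from the conventional [k1, k2, p1, p2, k3] ordering."""
        k1, k2, p1, p2, k3 = (list(coeffs) + [0.0] * 5)[:5]
        return cls(k1=k1, k2=k2, p1=p1, p2=p2, k3=k3)

    def as_list(self) -> list[float]:
        return [self.k1, self.k2, self.p1, self.p2, self.k3]


@dataclass(frozen=True)
class CameraPose:
    """Rigid camera pose: pitch ``gamma_deg`` about world X, translation ``t``.

    ``t`` is the world-frame position of the camera origin in meters.
    Positive ``gamma_deg`` follows the printed transform convention (optical
    axis raised above the world horizontal); the field-facing default used by
    the synthetic scenes is ``gamma_deg = -30`` (axis 30 deg below the
    horizontal, matching a camera mounted 60 deg to the ground).
    """

    gamma_deg: float = 30.0
    t: tuple[float, float, float] = (0.0, 2.0, 0.0)

    @property
    def translation(self) -> np.ndarray:
        return np.asarray(self.t, dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        """R_X(gamma): rotation of the camera frame about world X."""
        return rotation_about_x(self.gamma_deg)


@dataclass(frozen=True)
class PixelPoint:
    u: float
    v: float
    in_bounds: bool = True


@dataclass(frozen=True)
class CameraPoint:
    Xc: float
    Yc: float
    Zc: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.Xc, self.Yc, self.Zc], dtype=float)


@dataclass(frozen=True)
class WorldPoint:
    Xw: float
    Yw: float
    Zw: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.Xw, self.Yw, self.Zw], dtype=float)


def rotation_about_x(gamma_deg: float) -> np.ndarray:
    """Rotation matrix about the X axis by ``gamma_deg`` degrees.

    R_X(gamma) = [[1, 0, 0],
                  [0, cos g, -sin g],
                  [0, sin g,  cos g]]
    """
    g = np.deg2rad(gamma_deg)
    c, s = np.cos(g), np.sin(g)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def camera_to_world(p: CameraPoint, pose: CameraPose) -> WorldPoint:
    """P_W = R_X(gamma)^-1 . P_C + T."""
    w = pose.rotation.T @ p.xyz + pose.translation
    return WorldPoint(*w)


def world_to_camera(p: WorldPoint, pose: CameraPose) -> CameraPoint:
    """P_C = R_X(gamma) . (P_W - T); exact inverse of :func:`camera_to_world`."""
    c = pose.rotation @ (p.xyz - pose.translation)
    return CameraPoint(*c)


def transform_points_to_world(points_c: np.ndarray, pose: CameraPose) -> np.ndarray:
    """Vectorized camera->world for an (N, 3) array."""
    pts = np.atleast_2d(np.asarray(points_c, dtype=float))
    return pts @ pose.rotation + pose.translation  # (R^T @ p)^T = p^T @ R


def transform_points_to_camera(points_w: np.ndarray, pose: CameraPose) -> np.ndarray:
    """Vectorized world->camera for an (N, 3) array."""
    pts = np.atleast_2d(np.asarray(points_w, dtype=float))
    return (pts - pose.translation) @ pose.rotation.T


def _distort_normalized(
    x: np.ndarray, y: np.ndarray, dist: DistortionModel
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the radial-tangential model to normalized coordinates."""
    r2 = x * x + y * y
    radial = 1.0 + dist.k1 * r2 + dist.k2 * r2 * r2 + dist.k3 * r2 * r2 * r2
    xd = x * radial + 2.0 * dist.p1 * x * y + dist.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + dist.p1 * (r2 + 2.0 * y * y) + 2.0 * dist.p2 * x * y
    return xd, yd


def project_to_pixel(
    p: CameraPoint, K: Intrinsics, dist: DistortionModel | None = None
) -> PixelPoint:
    """Project a camera-frame point to pixel coordinates.

    With zero distortion this is u = fx*Xc/Zc + cx, v = fy*Yc/Zc + cy; with a
    nonzero model the radial-tangential polynomial is applied to the
    normalized coordinates first.  Raises
    :class:`~rowturn.errors.PointBehindCameraError` when Zc <= 0.
    """
    if not p.Zc > 0:
        raise PointBehindCameraError(f"point has non-positive depth Zc={p.Zc}")
    x = p.Xc / p.Zc
    y = p.Yc / p.Zc
    if dist is not None and not dist.is_identity:
        x, y = _distort_normalized(np.asarray(x), np.asarray(y), dist)
        x, y = float(x), float(y)
    u = K.fx * x + K.cx
    v = K.fy * y + K.cy
    in_bounds = 0 <= u < K.image_width and 0 <= v < K.image_height
    return PixelPoint(u, v, in_bounds)


def project_points(
    points_c: np.ndarray, K: Intrinsics, dist: DistortionModel | None = None
) -> np.ndarray:
    """Vectorized projection of an (N, 3) camera-frame array to (N, 2) pixels.

    The caller must have removed points with Zc <= 0.
    """
    pts = np.atleast_2d(np.asarray(points_c, dtype=float))
    if np.any(pts[:, 2] <= 0):
        raise PointBehindCameraError("project_points received Zc <= 0")
    x = pts[:, 0] / pts[:, 2]
    y = pts[:, 1] / pts[:, 2]
    if dist is not None and not dist.is_identity:
        x, y = _distort_normalized(x, y, dist)
    return np.column_stack([K.fx * x + K.cx, K.fy * y + K.cy])


def clamp_to_image(p: PixelPoint, K: Intrinsics) -> PixelPoint:
    """Clamp to [0, W-1] x [0, H-1]; ``in_bounds=False`` records clamping."""
    u = min(max(p.u, 0.0), K.image_width - 1.0)
    v = min(max(p.v, 0.0), K.image_height - 1.0)
    clamped = (u != p.u) or (v != p.v)
    return PixelPoint(u, v, in_bounds=not clamped)
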