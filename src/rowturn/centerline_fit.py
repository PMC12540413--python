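"""Per-row centerline fitting and angular-deviation evaluation.

Each contour's centroid set is summarized by an orthogonal (total)
least-squares line: the point (x0, y0) is the centroid mean and the
direction (vx, vy) is the principal axis of the scatter, minimizing the
perpendicular sum of squared distances.  Orientations are undirected: all
angle comparisons are taken modulo 180 deg and reported in (-90, 90]
relative to the horizontal image axis (v pointing down).

Accuracy against a ground-truth "standard line" (the segment joining the
midpoints of a row's top and bottom edges) is expressed as a signed
deviation theta: negative when the fitted line deviates to the left of the
standard line, positive to the right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import NearVerticalLineError, UnderdeterminedFitError
from .row_features import FeaturePoint

__all__ = [
    "FittedLine",
    "StandardLine",
    "AngleDeviation",
    "DeviationSummary",
    "fit_line",
    "line_endpoints",
    "vertical_endpoints",
    "line_angle",
    "orientation_from_endpoints",
    "angle_between",
    "summarize",
]

_VX_EPS = 1e-6


@dataclass(frozen=True)
class FittedLine:
    """Line x = x0 + vx*t, y = y0 + vy*t with unit direction, vy >= 0."""

    x0: float
    y0: float
    vx: float
    vy: float
    beta: float  # atan2(vy, vx), radians, in [0, pi)
    beta_deg: float
    p_start: tuple[float, float] | None = None  # at x = 0
    p_end: tuple[float, float] | None = None  # at x = W


@dataclass(frozen=True)
class StandardLine:
    """Ground-truth reference segment with endpoints in pixel coordinates."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if self.x1 == self.x2 and self.y1 == self.y2:
            raise ValueError("standard line endpoints must be distinct")

    @property
    def slope(self) -> float:
        """m = (y2 - y1)/(x2 - x1); +inf for a vertical segment."""
        if self.x2 == self.x1:
            return math.inf
        return (self.y2 - self.y1) / (self.x2 - self.x1)

    @property
    def orientation_deg(self) -> float:
        return orientation_from_endpoints(self.x1, self.y1, self.x2, self.y2)


@dataclass(frozen=True)
class AngleDeviation:
    """Signed deviation in degrees; negative = fitted line left of standard."""

    theta: float
    abs_theta: float


@dataclass(frozen=True)
class DeviationSummary:
    mean: float
    mae: float
    max_abs: float
    n: int


def _canonical(vx: float, vy: float) -> tuple[float, float]:
    """Flip the direction so vy >= 0, breaking ties toward vx > 0."""
    if vy < 0 or (vy == 0 and vx < 0):
        return -vx, -vy
    return vx, vy


def fit_line(points, width: int | None = None) -> FittedLine:
    """Orthogonal least-squares fit of a line through feature points.

    ``points`` is a sequence of :class:`FeaturePoint` or of (x, y) pairs.
    When ``width`` is given and the line is not near-vertical, the x=0 and
    x=W endpoints are attached.
    """
    points = list(points) if not isinstance(points, np.ndarray) else points
    if len(points) and isinstance(points[0], FeaturePoint):
        xy = np.array([[p.Cx, p.Cy] for p in points], dtype=float)
    else:
        xy = np.asarray(points, dtype=float).reshape(-1, 2)
    distinct = np.unique(xy, axis=0)
    if distinct.shape[0] < 2:
        raise UnderdeterminedFitError("need at least 2 distinct points")
    mean = xy.mean(axis=0)
    centered = xy - mean
    # Principal axis of the scatter = eigenvector of the 2x2 covariance with
    # the largest eigenvalue; this minimizes the perpendicular SSE.
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, int(np.argmax(eigvals))]
    vx, vy = _canonical(float(direction[0]), float(direction[1]))
    beta = math.atan2(vy, vx)
    line = FittedLine(
        x0=float(mean[0]), y0=float(mean[1]), vx=vx, vy=vy,
        beta=beta, beta_deg=math.degrees(beta),
    )
    if width is not None and abs(vx) >= _VX_EPS:
        p_start, p_end = line_endpoints(line, width)
        line = FittedLine(**{**line.__dict__, "p_start": p_start, "p_end": p_end})
    return line


def line_endpoints(line: FittedLine, W: int) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints where the line crosses x = 0 and x = W.

    P_start = (0, y0 - x0*vy/vx), P_end = (W, y0 + (W - x0)*vy/vx).  Raises
    for near-vertical lines; use :func:`vertical_endpoints` instead there.
    """
    if abs(line.vx) < _VX_EPS:
        raise NearVerticalLineError("|vx| too small for x=0 / x=W endpoints")
    slope = line.vy / line.vx
    p_start = (0.0, line.y0 - line.x0 * slope)
    p_end = (float(W), line.y0 + (W - line.x0) * slope)
    return p_start, p_end


def vertical_endpoints(line: FittedLine, H: int) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fallback endpoints at the top (y=0) and bottom (y=H) image edges."""
    if abs(line.vy) < _VX_EPS:
        raise NearVerticalLineError("line is horizontal; use line_endpoints")
    inv_slope = line.vx / line.vy
    top = (line.x0 - line.y0 * inv_slope, 0.0)
    bottom = (line.x0 + (H - line.y0) * inv_slope, float(H))
    return top, bottom


def _wrap_orientation(deg: float) -> float:
    """Wrap an undirected orientation into (-90, 90]."""
    d = math.fmod(deg, 180.0)
    if d > 90.0:
        d -= 180.0
    elif d <= -90.0:
        d += 180.0
    return d


def line_angle(line: FittedLine) -> float:
    """Orientation of the fitted line relative to the horizontal axis.

    Degrees in (-90, 90], from the two-argument arctangent of (vy, vx).
    """
    return _wrap_orientation(math.degrees(math.atan2(line.vy, line.vx)))


def orientation_from_endpoints(x1: float, y1: float, x2: float, y2: float) -> float:
    """Undirected orientation in (-90, 90] of the segment (x1,y1)-(x2,y2)."""
    return _wrap_orientation(math.degrees(math.atan2(y2 - y1, x2 - x1)))


def angle_between(fitted: FittedLine, standard: StandardLine) -> AngleDeviation:
    """Signed angular deviation of the fitted line from the standard line.

    theta = fitted orientation minus standard orientation, wrapped to
    (-90, 90]; in image coordinates (v down) a negative theta means the
    fitted line's upper end sits at smaller u than the standard line's,
    i.e. it deviates to the left.  The orientation-difference formulation
    stays finite for perpendicular pairs (m1*m2 = -1).
    """
    theta = _wrap_orientation(line_angle(fitted) - standard.orientation_deg)
    return AngleDeviation(theta=theta, abs_theta=abs(theta))


def summarize(devs) -> DeviationSummary:
    """Mean signed deviation, mean absolute error, and max absolute error.

    ``devs`` is a sequence of :class:`AngleDeviation` or of plain signed
    degrees.
    """
    values = np.array(
        [d.theta if isinstance(d, AngleDeviation) else float(d) for d in devs]
    )
    if values.size == 0:
        raise UnderdeterminedFitError("cannot summarize an empty deviation list")
    return DeviationSummary(
        mean=float(values.mean()),
        mae=float(np.abs(values).mean()),
        max_abs=float(np.abs(values).max()),
        n=int(values.size),
    )
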