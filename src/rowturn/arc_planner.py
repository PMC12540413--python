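"""Arc steering-path synthesis in the world frame.

Given the headland's world position (Xw, Zw) on the ground plane and the
crop-row azimuth beta_deg, the turn is a circular arc of radius
R = min(|Xw|, |Zw|) (constrained to exceed the vehicle's minimum turning
radius), centered at

    O = (sign(Xw)*R, 0, Zw - R)   when R = |Xw| < |Zw|
    O = (sign(Xw)*R, 0, 0)        when R = |Zw| <= |Xw|

and swept through alpha = beta_deg (beta_deg > 0) or 180 + beta_deg
(beta_deg < 0) degrees.  The arc is anchored so its start lies on the
vehicle's forward axis (the X = 0 line); a straight lead-in connects the
origin to that start point when they differ.  The concatenated waypoints
are smoothed by a natural cubic spline on (X, Z) parameterized by
cumulative chord length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DegenerateAzimuthError, InfeasibleTurnError

__all__ = [
    "PlannerInput",
    "ArcSpec",
    "SplineSegment",
    "PlannedPath",
    "arc_radius",
    "arc_center",
    "arc_angle",
    "sample_arc",
    "plan_turn",
]

DEFAULT_R_MIN = 1.5
DEFAULT_N_SAMPLES = 100


@dataclass(frozen=True)
class PlannerInput:
    """Target world position, row azimuth, and minimum turning radius."""

    Xw: float
    Zw: float
    beta_deg: float
    R_min: float = DEFAULT_R_MIN

    def __post_init__(self) -> None:
        if self.R_min <= 0:
            raise ValueError("R_min must be positive")
        if self.Xw == 0.0 and self.Zw == 0.0:
            raise ValueError("target cannot be the origin")
        if not (-180.0 < self.beta_deg <= 180.0):
            raise ValueError("beta_deg must lie in (-180, 180]")


@dataclass(frozen=True)
class ArcSpec:
    """Turn radius R (m), center O (world, Y=0), swept angle alpha (deg)."""

    R: float
    O: tuple[float, float, float]
    alpha_deg: float
    turn_direction: str  # "left" (Xw > 0) or "right" (Xw < 0)

    @property
    def sign(self) -> float:
        """+1 for a left turn (target in the +X half), -1 for right."""
        return 1.0 if self.turn_direction == "left" else -1.0


@dataclass(frozen=True)
class SplineSegment:
    """One cubic piece a + b*dx + c*dx^2 + d*dx^3 on [x_lo, x_hi]."""

    a: float
    b: float
    c: float
    d: float
    x_lo: float
    x_hi: float
    channel: str  # "x" or "z"

    def __call__(self, x: float) -> float:
        dx = x - self.x_lo
        return self.a + self.b * dx + self.c * dx * dx + self.d * dx**3


@dataclass
class PlannedPath:
    """Lead-in + arc waypoints with their chord-length spline smoothing."""

    waypoints: np.ndarray  # (N, 3) world points, Y = 0
    spline: list[SplineSegment]
    source: ArcSpec
    terminal_offset: float = 0.0  # |terminal waypoint - target|, diagnostic
    _cs_x: CubicSpline | None = field(default=None, repr=False)
    _cs_z: CubicSpline | None = field(default=None, repr=False)
    _knots: np.ndarray | None = field(default=None, repr=False)

    def evaluate(self, n: int) -> np.ndarray:
        """Resample the smoothed path at n points uniform in chord length."""
        s = np.linspace(self._knots[0], self._knots[-1], n)
        return np.column_stack(
            [self._cs_x(s), np.zeros(n), self._cs_z(s)]
        )


def arc_radius(inp: PlannerInput) -> float:
    """R = min(|Xw|, |Zw|); infeasible when R <= R_min."""
    R = min(abs(inp.Xw), abs(inp.Zw))
    if R <= inp.R_min:
        raise InfeasibleTurnError(
            f"turn radius {R:.3f} m does not exceed R_min={inp.R_min:.3f} m"
        )
    return R


def arc_center(inp: PlannerInput, R: float) -> np.ndarray:
    """Arc center per the lateral/forward case split (Y = 0 plane)."""
    sign = 1.0 if inp.Xw > 0 else -1.0
    if abs(inp.Xw) < abs(inp.Zw):  # R = |Xw|
        return np.array([sign * R, 0.0, inp.Zw - R])
    return np.array([sign * R, 0.0, 0.0])  # R = |Zw|, including equality


def arc_angle(beta_deg: float) -> float:
    """Swept angle alpha: beta_deg if positive, else 180 + beta_deg."""
    if beta_deg == 0.0:
        raise DegenerateAzimuthError("row azimuth of 0 deg leaves alpha undefined")
    return beta_deg if beta_deg > 0 else 180.0 + beta_deg


def sample_arc(spec: ArcSpec, n: int = DEFAULT_N_SAMPLES) -> np.ndarray:
    """n points P(t) = O + R*(-sign*cos t, 0, sin t), t uniform in [0, alpha].

    P(0) lies on the vehicle's forward axis (X = 0) whenever |O_x| = R.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    t = np.deg2rad(np.linspace(0.0, spec.alpha_deg, n))
    O = np.asarray(spec.O, dtype=float)
    pts = np.column_stack(
        [
            O[0] - spec.sign * spec.R * np.cos(t),
            np.zeros(n),
            O[2] + spec.R * np.sin(t),
        ]
    )
    return pts


def _extract_segments(cs: CubicSpline, channel: str) -> list[SplineSegment]:
    segs = []
    for i in range(cs.c.shape[1]):
        d, c, b, a = cs.c[:, i]
        segs.append(
            SplineSegment(a=float(a), b=float(b), c=float(c), d=float(d),
                          x_lo=float(cs.x[i]), x_hi=float(cs.x[i + 1]),
                          channel=channel)
        )
    return segs


def plan_turn(inp: PlannerInput, n: int = DEFAULT_N_SAMPLES) -> PlannedPath:
    """Full turn path: straight lead-in, circular arc, spline smoothing.

    The lead-in runs from the world origin to the arc's start point at the
    same sample spacing as the arc; it is empty when the two coincide (the
    forward-limited R = |Zw| cases).  The waypoint chain is interpolated by
    a natural cubic spline in X and Z over cumulative chord length, giving
    C2 continuity at every interior knot.
    """
    R = arc_radius(inp)
    O = arc_center(inp, R)
    alpha = arc_angle(inp.beta_deg)
    spec = ArcSpec(
        R=R,
        O=(float(O[0]), float(O[1]), float(O[2])),
        alpha_deg=alpha,
        turn_direction="left" if inp.Xw > 0 else "right",
    )
    arc_pts = sample_arc(spec, n)
    start = arc_pts[0]
    lead_len = float(np.linalg.norm(start))
    if lead_len > 1e-12:
        arc_step = np.deg2rad(alpha) * R / (n - 1)
        n_lead = max(2, int(math.ceil(lead_len / max(arc_step, 1e-9))) + 1)
        lead = np.linspace([0.0, 0.0, 0.0], start, n_lead)
        waypoints = np.vstack([lead[:-1], arc_pts])
    else:
        waypoints = arc_pts
    target = np.array([inp.Xw, 0.0, inp.Zw])
    terminal_offset = float(np.linalg.norm(waypoints[-1] - target))

    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(waypoints, axis=0), axis=1))]
    )
    cs_x = CubicSpline(chord, waypoints[:, 0], bc_type="natural")
    cs_z = CubicSpline(chord, waypoints[:, 2], bc_type="natural")
    segments = _extract_segments(cs_x, "x") + _extract_segments(cs_z, "z")
    return PlannedPath(
        waypoints=waypoints,
        spline=segments,
        source=spec,
        terminal_offset=terminal_offset,
        _cs_x=cs_x,
        _cs_z=cs_z,
        _knots=chord,
    )
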