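"""Exception hierarchy for the rowturn pipeline.

Every stage raises a specific subclass of :class:`RowturnError` so the CLI can
map failures to distinct exit codes and name the failing stage.
"""


class RowturnError(Exception):
    """Base class for all rowturn-specific failures."""


class InvalidInputError(RowturnError):
    """Malformed or empty input (image, mask, mismatched dimensions)."""


class PointBehindCameraError(RowturnError):
    """Projection requested for a point with non-positive camera depth."""


class InvalidDisparityError(RowturnError):
    """Disparity value that cannot be converted to a depth (d <= 0)."""


class UnlocalizableDetectionError(RowturnError):
    """No valid disparity inside the core of a detection's bounding box."""


class UndefinedRelativeErrorError(RowturnError):
    """Relative localization error requested against the origin."""


class InvalidScheduleError(RowturnError):
    """Morphology schedule producing a kernel dimension < 1."""


class InvalidGeometryError(RowturnError):
    """ROI strip geometry that cannot fit inside the image."""


class UnderdeterminedFitError(RowturnError):
    """Line fit requested with fewer than two distinct points."""


class NearVerticalLineError(RowturnError):
    """Endpoint computation at x=0 / x=W for a (near-)vertical line."""


class InfeasibleTurnError(RowturnError):
    """Arc radius at or below the vehicle's minimum turning radius."""


class DegenerateAzimuthError(RowturnError):
    """Row azimuth of exactly 0 degrees: the arc span is undefined."""


class PathNotVisibleError(RowturnError):
    """Every planned waypoint lies behind the camera."""


class GenerationError(RowturnError):
    """Synthetic scene configuration that cannot be rendered."""
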