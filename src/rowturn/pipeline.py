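"""Stage orchestration: segmentation -> features -> centerline -> localization
-> planning -> projection, with truth-based evaluation helpers.

This is the library layer behind the ``rowturn run`` / ``rowturn evaluate``
commands and the synthetic-scene benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .arc_planner import PlannedPath, PlannerInput, plan_turn
from .centerline_fit import (
    AngleDeviation,
    FittedLine,
    StandardLine,
    angle_between,
    fit_line,
    line_angle,
)
from .config import PipelineConfig
from .errors import InvalidInputError, RowturnError, UnderdeterminedFitError
from .path_visualization import ProjectedPath, draw_path, project_path
from .row_features import extract_feature_points
from .row_segmentation import (
    BinaryMask,
    ContourSet,
    default_min_area,
    extract_contours,
    green_mask,
    open_schedule,
)
from .stereo_locate import Detection, DisparityMap, Localization3D, locate_detection

log = logging.getLogger("rowturn")

__all__ = [
    "PipelineResult",
    "segment_rows",
    "fit_rows",
    "match_rows",
    "headland_stub",
    "run_pipeline",
    "recover_orientations",
]


@dataclass
class PipelineResult:
    mask: BinaryMask
    contours: ContourSet
    features: dict[int, list]
    lines: dict[int, FittedLine]
    orientations_deg: dict[int, float]
    beta_deg: float | None = None
    localization: Localization3D | None = None
    path: PlannedPath | None = None
    projection: ProjectedPath | None = None
    overlay: np.ndarray | None = None
    counts: dict = field(default_factory=dict)


def segment_rows(image: np.ndarray, config: PipelineConfig) -> tuple[BinaryMask, ContourSet]:
    """HSV threshold, staged opening, and contour extraction."""
    seg = config.segmentation
    mask = open_schedule(green_mask(image, seg.thresholds()), seg.morphology())
    min_area = seg.contour_min_area
    if min_area is None:
        min_area = default_min_area(mask.width, mask.height)
    return mask, extract_contours(mask, min_area)


def fit_rows(grouped: dict, width: int) -> tuple[dict[int, FittedLine], dict[int, float]]:
    """Fit a centerline per contour; contours with < 2 centroids are skipped."""
    lines: dict[int, FittedLine] = {}
    orientations: dict[int, float] = {}
    for cid, pts in grouped.items():
        try:
            line = fit_line(pts, width=width)
        except UnderdeterminedFitError:
            continue
        lines[cid] = line
        orientations[cid] = line_angle(line)
    return lines, orientations


def _u_at(line: FittedLine, y: float) -> float:
    if abs(line.vy) < 1e-9:
        return line.x0
    return line.x0 + (y - line.y0) * line.vx / line.vy


def _standard_u_at(sl: StandardLine, y: float) -> float:
    if sl.y2 == sl.y1:
        return 0.5 * (sl.x1 + sl.x2)
    t = (y - sl.y1) / (sl.y2 - sl.y1)
    return sl.x1 + t * (sl.x2 - sl.x1)


def match_rows(
    lines: dict[int, FittedLine], standards: list[StandardLine]
) -> list[tuple[int, int, AngleDeviation]]:
    """Greedy one-to-one matching of fitted lines to standard lines.

    Lines are paired by the horizontal distance between them evaluated at
    the middle of each standard line's vertical span; each pairing yields
    the signed angular deviation.
    """
    candidates = []
    for cid, line in lines.items():
        for ridx, sl in enumerate(standards):
            y_mid = 0.5 * (sl.y1 + sl.y2)
            cost = abs(_u_at(line, y_mid) - _standard_u_at(sl, y_mid))
            candidates.append((cost, cid, ridx))
    candidates.sort()
    used_c: set[int] = set()
    used_r: set[int] = set()
    matches = []
    for cost, cid, ridx in candidates:
        if cid in used_c or ridx in used_r:
            continue
        used_c.add(cid)
        used_r.add(ridx)
        matches.append((cid, ridx, angle_between(lines[cid], standards[ridx])))
    return matches


def headland_stub(mask: BinaryMask, band_height: int = 28, gap: int = 6) -> Detection:
    """Non-learned headland heuristic: the band just past the row termination.

    With the default downward-pitched pose, rows recede toward larger v; the
    headland band sits below the last crop pixels, spanning the rows'
    horizontal extent.
    """
    ys, xs = np.nonzero(mask.values)
    if ys.size == 0:
        raise InvalidInputError("empty row mask; cannot place a headland box")
    v_end = int(ys.max())
    far = ys >= np.percentile(ys, 75)
    u_min, u_max = int(xs[far].min()), int(xs[far].max())
    v_min = min(v_end + gap, mask.height - 2)
    v_max = min(v_min + band_height, mask.height - 1)
    return Detection(bbox=(float(u_min), float(v_min), float(u_max), float(v_max)))


def run_pipeline(
    image: np.ndarray,
    disparity: DisparityMap,
    config: PipelineConfig | None = None,
    detections: list[Detection] | None = None,
) -> PipelineResult:
    """Run the full three-stage pipeline on one frame.

    Stages append to the result as they succeed; typed exceptions from a
    stage propagate to the caller (the CLI maps them to exit codes).
    """
    config = config or PipelineConfig()
    if image.shape[:2] != disparity.values.shape:
        raise InvalidInputError("image and disparity dimensions differ")
    K = config.camera.intrinsics()
    pose = config.camera.pose()
    mask, contours = segment_rows(image, config)
    feat = config.features
    grouped = extract_feature_points(
        contours, mask.height, mask.width,
        feat.strip_height, feat.strip_interval, feat.region_min_area,
    )
    lines, orientations = fit_rows(grouped, mask.width)
    result = PipelineResult(
        mask=mask, contours=contours, features=grouped,
        lines=lines, orientations_deg=orientations,
    )
    n_points = sum(len(p) for p in grouped.values())
    result.counts.update(contours=len(contours), feature_points=n_points,
                         fitted_lines=len(lines))
    log.info("segmentation: %d contours, %d feature points, %d lines",
             len(contours), n_points, len(lines))
    if orientations:
        result.beta_deg = float(np.mean(list(orientations.values())))

    try:
        dets = detections if detections is not None else [headland_stub(mask)]
        headlands = [d for d in dets if d.label == "headland"] or dets
        result.localization = locate_detection(
            headlands[0], disparity, config.stereo.params(), K, pose
        )
        wp = result.localization.world_point
        log.info("headland at world (%.3f, %.3f, %.3f)", wp.Xw, wp.Yw, wp.Zw)

        if result.beta_deg is None:
            raise UnderdeterminedFitError("no fitted rows: azimuth unavailable")
        inp = PlannerInput(Xw=wp.Xw, Zw=wp.Zw, beta_deg=result.beta_deg,
                           R_min=config.planner.R_min)
        result.path = plan_turn(inp, n=config.planner.n_samples)
        result.projection = project_path(result.path, pose, K,
                                         config.camera.distortion_model())
    except RowturnError as exc:
        # let callers salvage the stages that did succeed
        exc.partial_result = result
        raise
    result.counts.update(
        waypoints=len(result.path.waypoints),
        dropped=result.projection.dropped_count,
        clamped=result.projection.clamped_count,
    )
    log.info("path: %d waypoints, %d dropped, %d clamped",
             *(result.counts[k] for k in ("waypoints", "dropped", "clamped")))
    result.overlay = _render_overlay(image, result, config)
    return result


def _render_overlay(image: np.ndarray, result: PipelineResult,
                    config: PipelineConfig) -> np.ndarray:
    from skimage.draw import line as draw_line

    out = draw_path(image, result.projection, config.io.marker_radius,
                    tuple(config.io.path_color))
    h, w = out.shape[:2]
    for ln in result.lines.values():
        # draw along the vertical extent of the image
        try:
            if abs(ln.vy) > abs(ln.vx):
                p0 = (_u_at(ln, 0.0), 0.0)
                p1 = (_u_at(ln, h - 1.0), h - 1.0)
            else:
                p0 = (0.0, ln.y0 - ln.x0 * ln.vy / ln.vx)
                p1 = (w - 1.0, ln.y0 + (w - 1 - ln.x0) * ln.vy / ln.vx)
        except ZeroDivisionError:
            continue
        r0, c0 = int(np.clip(p0[1], 0, h - 1)), int(np.clip(p0[0], 0, w - 1))
        r1, c1 = int(np.clip(p1[1], 0, h - 1)), int(np.clip(p1[0], 0, w - 1))
        rr, cc = draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        out[rr[keep], cc[keep]] = config.io.fitted_line_color
    return out


def recover_orientations(scene, config: PipelineConfig | None = None):
    """Run segmentation/features/fitting on a synthetic scene and compare
    the recovered row orientations against the recorded truth.

    Returns a list of (true_deg, fitted_deg, signed_deviation_deg) for the
    matched rows.
    """
    config = config or PipelineConfig()
    mask, contours = segment_rows(scene.rgb, config)
    feat = config.features
    grouped = extract_feature_points(
        contours, mask.height, mask.width,
        feat.strip_height, feat.strip_interval, feat.region_min_area,
    )
    lines, orientations = fit_rows(grouped, mask.width)
    matches = match_rows(lines, scene.truth.standard_lines)
    out = []
    for cid, ridx, dev in matches:
        out.append((scene.truth.true_orientations_deg[ridx],
                    orientations[cid], dev.theta))
    return out
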