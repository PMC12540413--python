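"""Seeded synthetic field scenes with exact ground truth.

The generator emulates a ridged soybean planting viewed from a machine-
mounted stereo camera: three rows per ridge on the platform centerline and
at +/-0.225 m, ridge base 1.100 m, platform 0.700 m, camera 2 m above the
ground pitched 30 deg toward it.  Every pixel's depth comes from the exact
ray/ground-plane intersection under the same transform conventions the rest
of the package uses, so the rendered disparity map, the recorded headland
position, and the projection pipeline are consistent to floating-point
precision.

Plants are filled discs of jittered green hue laid along each row with a
configurable spacing, dropped independently with a missing-plant
probability; clutter adds beige straw streaks (outside the green hue band)
and a smooth multiplicative shadow field (scales V, leaves H and S alone).
Plant height is ignored: depth is ground-plane depth, a good approximation
for V3-V8 canopies seen from 2 m.

Identical (config, seed) pairs give bit-identical RGB, disparity and truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from skimage import color

from .camera_geometry import CameraPose, Intrinsics, PixelPoint, camera_to_world
from .centerline_fit import StandardLine, orientation_from_endpoints
from .errors import GenerationError
from .stereo_locate import Detection, DisparityMap, StereoParams, pixel_to_camera_3d

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "Scene",
    "CLUTTER_PRESETS",
    "render_scene",
    "make_fixture_suite",
]

#: straw streak count, shadow strength, missing-plant probability
CLUTTER_PRESETS: dict[str, tuple[int, float, float]] = {
    "none": (0, 0.0, 0.0),
    "low": (6, 0.10, 0.02),
    "medium": (18, 0.25, 0.08),
    "high": (32, 0.40, 0.15),
}


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic scene.

    Lengths are meters, angles degrees.  ``row_azimuth_deg`` is the world-
    frame heading of the rows in the ground plane, measured from the +X_W
    axis (90 = straight ahead along +Z_W).  ``camera_pitch_deg`` is negative
    for the field-facing camera (optical axis below the horizontal).
    """

    image_width: int = 640
    image_height: int = 480
    fx: float = 400.0
    fy: float = 400.0
    cx: float = 320.0
    cy: float = 240.0
    camera_height: float = 2.0
    camera_pitch_deg: float = -30.0
    stereo_f: float = 400.0
    stereo_B: float = 0.075
    ridge_base_width: float = 1.100
    platform_width: float = 0.700
    ridge_height: float = 0.250
    row_offsets: tuple[float, ...] = (-0.225, 0.0, 0.225)
    row_azimuth_deg: float = 90.0
    row_start: float = 1.2  # along-row start of planting, m from the origin
    row_end: float = 5.0  # along-row termination (headland beyond)
    plant_spacing: float = 0.08
    plant_radius: float = 0.07
    straw_streaks: int = 6
    shadow_strength: float = 0.10
    missing_plant_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "camera_height", "stereo_f", "stereo_B", "ridge_base_width",
            "platform_width", "ridge_height", "plant_spacing", "plant_radius",
        ):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if not 0.0 <= self.missing_plant_prob <= 1.0:
            raise GenerationError("missing_plant_prob must be in [0, 1]")
        if not 0.0 <= self.shadow_strength < 1.0:
            raise GenerationError("shadow_strength must be in [0, 1)")
        if self.row_end <= self.row_start:
            raise GenerationError("row_end must exceed row_start")

    @property
    def intrinsics(self) -> Intrinsics:
        return Intrinsics(self.fx, self.fy, self.cx, self.cy,
                          self.image_width, self.image_height)

    @property
    def pose(self) -> CameraPose:
        return CameraPose(gamma_deg=self.camera_pitch_deg,
                          t=(0.0, self.camera_height, 0.0))

    @property
    def stereo(self) -> StereoParams:
        return StereoParams(f=self.stereo_f, B=self.stereo_B)


@dataclass
class SceneTruth:
    """Exact per-scene ground truth recorded by the renderer."""

    standard_lines: list[StandardLine]
    true_orientations_deg: list[float]
    crop_mask: np.ndarray  # bool, HxW
    row_id_map: np.ndarray  # int8, -1 = not crop
    headland_bbox: Detection
    headland_world: tuple[float, float, float]
    depth: np.ndarray  # float64 meters, 0 = no ground intersection
    config: SceneConfig

    def to_json_dict(self) -> dict:
        return {
            "standard_lines": [
                [sl.x1, sl.y1, sl.x2, sl.y2] for sl in self.standard_lines
            ],
            "true_orientations_deg": self.true_orientations_deg,
            "headland_bbox": list(self.headland_bbox.bbox),
            "headland_world": list(self.headland_world),
            "config": asdict(self.config),
        }


@dataclass
class Scene:
    rgb: np.ndarray  # uint8 HxWx3
    disparity: DisparityMap
    truth: SceneTruth

    def write(self, out_dir: str | Path) -> None:
        """Write image.png, disparity.tif and truth.json to a directory."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out / "image.png", self.rgb)
        self.disparity.save(out / "disparity.tif")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth.to_json_dict(), fh, indent=1)


def _ground_geometry(cfg: SceneConfig):
    """Per-pixel ground-plane intersection: world X/Z, camera depth, mask."""
    K = cfg.intrinsics
    u = np.arange(cfg.image_width, dtype=np.float64)
    v = np.arange(cfg.image_height, dtype=np.float64)
    xn = (u[None, :] - K.cx) / K.fx
    yn = (v[:, None] - K.cy) / K.fy
    g = np.deg2rad(cfg.camera_pitch_deg)
    # world direction of the pixel ray: R_X(g)^T . (xn, yn, 1)
    dwy = np.cos(g) * yn + np.sin(g)
    dwz = -np.sin(g) * yn + np.cos(g)
    dwy_full = np.broadcast_to(dwy, (cfg.image_height, cfg.image_width))
    ground = dwy_full < -1e-9
    depth = np.zeros((cfg.image_height, cfg.image_width))
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -cfg.camera_height / dwy_full
    depth[ground] = s[ground]
    Xw = np.where(ground, s * xn, 0.0)
    Zw = np.where(ground, s * dwz, 0.0)
    return Xw, Zw, depth, ground


def render_scene(cfg: SceneConfig) -> Scene:
    """Render one scene: RGB image, exact disparity map, ground truth."""
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_height, cfg.image_width
    Xw, Zw, depth, ground = _ground_geometry(cfg)

    # --- base HSV canvas: soil on the ground, flat gray sky elsewhere ---
    hue = np.where(ground, 20.0 + 15.0 * rng.random((H, W)), 210.0)
    sat = np.where(ground, 0.30 + 0.20 * rng.random((H, W)), 0.05)
    val = np.where(ground, 0.35 + 0.20 * rng.random((H, W)), 0.80)

    # --- straw streaks (beige, hue outside the green band), soil only ---
    if cfg.straw_streaks > 0:
        from skimage.draw import line as draw_line

        gr, gc = np.nonzero(ground)
        for _ in range(cfg.straw_streaks):
            i0, i1 = rng.integers(0, gr.size, size=2)
            r0, c0 = int(gr[i0]), int(gc[i0])
            length = int(rng.integers(20, 80))
            ang = rng.uniform(0, np.pi)
            r1 = int(np.clip(r0 + length * np.sin(ang), 0, H - 1))
            c1 = int(np.clip(c0 + length * np.cos(ang), 0, W - 1))
            h_straw = rng.uniform(40.0, 60.0)
            for dr in (-1, 0, 1):
                rr, cc = draw_line(int(np.clip(r0 + dr, 0, H - 1)), c0,
                                   int(np.clip(r1 + dr, 0, H - 1)), c1)
                keep = ground[rr, cc]
                rr, cc = rr[keep], cc[keep]
                hue[rr, cc] = h_straw
                sat[rr, cc] = 0.45
                val[rr, cc] = 0.70

    # --- crop rows: jittered green discs along each row line ---
    az = np.deg2rad(cfg.row_azimuth_deg)
    ux, uz = np.cos(az), np.sin(az)  # along-row unit vector in (X, Z)
    nx, nz = -uz, ux  # lateral unit vector
    along = Xw * ux + Zw * uz
    lat = Xw * nx + Zw * nz
    k0 = int(np.ceil(cfg.row_start / cfg.plant_spacing))
    k1 = int(np.floor(cfg.row_end / cfg.plant_spacing))
    n_plants = k1 - k0 + 1
    if n_plants < 2:
        raise GenerationError("row extent holds fewer than 2 plants")
    k_idx = np.clip(np.round(along / cfg.plant_spacing).astype(int), k0, k1)
    center_along = k_idx * cfg.plant_spacing
    r2 = cfg.plant_radius**2
    row_id = np.full((H, W), -1, dtype=np.int8)
    # plant presence and hue jitter drawn in a fixed order for determinism
    present = [rng.random(n_plants) >= cfg.missing_plant_prob
               for _ in cfg.row_offsets]
    hue_jit = 95.0 + 45.0 * rng.random((H, W))
    sat_jit = 0.55 + 0.35 * rng.random((H, W))
    val_jit = 0.45 + 0.30 * rng.random((H, W))
    for ri, off in enumerate(cfg.row_offsets):
        dlat = lat - off
        in_plant = (
            ground
            & (along >= cfg.row_start)
            & (along <= cfg.row_end)
            & ((along - center_along) ** 2 + dlat**2 <= r2)
            & present[ri][k_idx - k0]
        )
        row_id[in_plant] = ri
    crop = row_id >= 0
    hue = np.where(crop, hue_jit, hue)
    sat = np.where(crop, sat_jit, sat)
    val = np.where(crop, val_jit, val)

    # --- smooth multiplicative shadow: scales V, preserves H and S ---
    if cfg.shadow_strength > 0:
        uu, vv = np.meshgrid(np.arange(W) / W, np.arange(H) / H)
        a, b = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        gfield = 0.5 + 0.5 * np.sin(2 * np.pi * (a * uu + b * vv) + phase)
        val = val * (1.0 - cfg.shadow_strength * gfield)

    hsv = np.stack([hue / 360.0, sat, val], axis=-1)
    rgb = np.round(color.hsv2rgb(hsv) * 255.0).astype(np.uint8)

    # --- exact disparity from ground depth ---
    disparity = np.zeros((H, W))
    disparity[ground] = cfg.stereo_f * cfg.stereo_B / depth[ground]

    # --- standard lines: join midpoints of each row's top and bottom edges ---
    standard_lines: list[StandardLine] = []
    orientations: list[float] = []
    for ri in range(len(cfg.row_offsets)):
        ys, xs = np.nonzero(row_id == ri)
        if ys.size == 0 or ys.min() == ys.max():
            raise GenerationError(f"row {ri} not visible in the rendered scene")
        # The "edge midpoint" is taken over a thin end slice of the band
        # rather than the single extreme pixel row: the extreme row of a
        # tilted band is its corner tip, whose midpoint sits off the row
        # centerline and would bias the reference orientation.
        extent = int(ys.max() - ys.min())
        h_slice = max(3, extent // 20)
        top = ys <= ys.min() + h_slice
        bot = ys >= ys.max() - h_slice
        sl = StandardLine(
            x1=float(xs[top].mean()), y1=float(ys[top].mean()),
            x2=float(xs[bot].mean()), y2=float(ys[bot].mean()),
        )
        standard_lines.append(sl)
        orientations.append(orientation_from_endpoints(sl.x1, sl.y1, sl.x2, sl.y2))

    # --- headland: row-termination band across the ridge base ---
    half_base = 0.5 * cfg.ridge_base_width
    band = (
        ground
        & (along > cfg.row_end + 0.15)
        & (along <= cfg.row_end + 0.95)
        & (np.abs(lat) <= half_base)
    )
    ys, xs = np.nonzero(band)
    if ys.size == 0:
        raise GenerationError("headland band not visible in the rendered scene")
    u_min, u_max = int(xs.min()), int(xs.max())
    v_min, v_max = int(ys.min()), int(ys.max())
    # force an integer bbox center so localization truth is exact
    if (u_min + u_max) % 2:
        u_max -= 1
    if (v_min + v_max) % 2:
        v_max -= 1
    bbox = Detection(bbox=(float(u_min), float(v_min), float(u_max), float(v_max)))
    uc, vc = int(bbox.center[0]), int(bbox.center[1])
    cam_pt = pixel_to_camera_3d(PixelPoint(float(uc), float(vc)),
                                depth[vc, uc], cfg.intrinsics)
    world_pt = camera_to_world(cam_pt, cfg.pose)
    truth = SceneTruth(
        standard_lines=standard_lines,
        true_orientations_deg=orientations,
        crop_mask=crop,
        row_id_map=row_id,
        headland_bbox=bbox,
        headland_world=(world_pt.Xw, world_pt.Yw, world_pt.Zw),
        depth=depth,
        config=cfg,
    )
    return Scene(rgb=rgb, disparity=DisparityMap(disparity), truth=truth)


def _scene_seed(base_seed: int, i: int) -> int:
    """Stable child seed below 2**31."""
    return int(np.random.SeedSequence(entropy=base_seed,
                                      spawn_key=(i,)).generate_state(1)[0] % 2**31)


def make_fixture_suite(
    n: int,
    base_seed: int,
    out_dir: str | Path | None = None,
    base_config: SceneConfig | None = None,
) -> list[Scene]:
    """Render ``n`` scenes spanning azimuths 60-120 deg and all clutter levels.

    Clutter cycles low/medium/high so every level appears at least once for
    n >= 3.  When ``out_dir`` is given each scene is written to
    ``scene_###/`` (image.png, disparity.tif, truth.json).
    """
    if n < 1:
        raise GenerationError("need at least one scene")
    base = base_config or SceneConfig()
    azimuths = np.linspace(60.0, 120.0, n) if n > 1 else np.array([90.0])
    levels = ["low", "medium", "high"]
    scenes = []
    for i in range(n):
        straw, shadow, missing = CLUTTER_PRESETS[levels[i % 3]]
        cfg = replace(
            base,
            row_azimuth_deg=float(azimuths[i]),
            straw_streaks=straw,
            shadow_strength=shadow,
            missing_plant_prob=missing,
            seed=_scene_seed(base_seed, i),
        )
        scene = render_scene(cfg)
        if out_dir is not None:
            scene.write(Path(out_dir) / f"scene_{i:03d}")
        scenes.append(scene)
    return scenes


def clutter_level(i: int) -> str:
    """Clutter level assigned to fixture index ``i`` by the suite cycle."""
    return ["low", "medium", "high"][i % 3]
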