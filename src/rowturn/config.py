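"""Pipeline configuration: strict, serializable, documented defaults.

The YAML/JSON schema mirrors the pipeline stages: ``camera`` (intrinsics,
distortion, pose), ``stereo`` (focal/baseline), ``segmentation`` (HSV band,
opening schedule, contour area), ``features`` (ROI strips, screening),
``planner`` (R_min, sampling) and ``io`` (overlay style).  Unknown keys are
rejected; ``PipelineConfig().dump(path)`` round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .camera_geometry import CameraPose, DistortionModel, Intrinsics
from .errors import RowturnError
from .row_segmentation import HsvThresholds, MorphologySchedule
from .stereo_locate import StereoParams

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(RowturnError):
    """Configuration file that fails schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CameraSection(_Strict):
    fx: float = 400.0
    fy: float = 400.0
    cx: float = 320.0
    cy: float = 240.0
    width: int = 640
    height: int = 480
    #: [k1, k2, p1, p2, k3]
    distortion: list[float] = [0.0, 0.0, 0.0, 0.0, 0.0]
    #: pitch about world X, degrees; negative points the axis at the ground
    gamma_deg: float = -30.0
    T: list[float] = [0.0, 2.0, 0.0]

    def intrinsics(self) -> Intrinsics:
        return Intrinsics(self.fx, self.fy, self.cx, self.cy, self.width, self.height)

    def distortion_model(self) -> DistortionModel:
        return DistortionModel.from_list(self.distortion)

    def pose(self) -> CameraPose:
        return CameraPose(gamma_deg=self.gamma_deg, t=tuple(self.T))


class StereoSection(_Strict):
    f: float = 400.0
    B: float = 0.075

    def params(self) -> StereoParams:
        return StereoParams(f=self.f, B=self.B)


class SegmentationSection(_Strict):
    h_min: float = 70.0
    h_max: float = 170.0
    s_min: float = 0.25
    s_max: float = 1.0
    v_min: float = 0.20
    v_max: float = 1.0
    schedule: list[int] = [1, 3, 5]
    #: contour area threshold in px^2; null = 500 scaled by image area / (640*480)
    contour_min_area: float | None = None

    def thresholds(self) -> HsvThresholds:
        return HsvThresholds(self.h_min, self.h_max, self.s_min, self.s_max,
                             self.v_min, self.v_max)

    def morphology(self) -> MorphologySchedule:
        return MorphologySchedule(iterations=tuple(self.schedule))


class FeaturesSection(_Strict):
    strip_height: int = 40
    strip_interval: int = 60
    region_min_area: float = 50.0


class PlannerSection(_Strict):
    R_min: float = 1.5
    n_samples: int = 100


class IoSection(_Strict):
    marker_radius: int = 3
    path_color: list[int] = [0, 255, 0]
    fitted_line_color: list[int] = [255, 255, 0]
    standard_line_color: list[int] = [255, 0, 0]


class PipelineConfig(_Strict):
    camera: CameraSection = CameraSection()
    stereo: StereoSection = StereoSection()
    segmentation: SegmentationSection = SegmentationSection()
    features: FeaturesSection = FeaturesSection()
    planner: PlannerSection = PlannerSection()
    io: IoSection = IoSection()

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML/JSON pipeline config; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return PipelineConfig.model_validate(raw)
    except (ValidationError, yaml.YAMLError) as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
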