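"""YAML run configuration: defaults, overlay, strict validation.

Unknown keys are rejected with an error naming the offending key, and
every block is validated against the owning module's invariants before any
command runs.  The full default configuration is defined here, in one
place.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .calibration import CameraSetup
from .grille import GrilleConfig


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CameraBlock(_Strict):
    image_width_px: int = Field(1920, gt=0)
    image_height_px: int = Field(1080, gt=0)
    boom_width_m: float = Field(3.3, gt=0)
    n_cameras: int = Field(2, gt=0)
    mount_height_m: float = Field(1.0, gt=0)

    def to_setup(self) -> CameraSetup:
        return CameraSetup(**self.model_dump())


class GrilleBlock(_Strict):
    n_cells: int = Field(11, ge=1)
    row_height_px: int = Field(60, ge=1)
    row_top_px: int | None = None
    area_threshold_px2: float = Field(0.0, ge=0)

    def to_config(self, camera: CameraBlock) -> GrilleConfig:
        return GrilleConfig(n_cells=self.n_cells,
                            image_width_px=camera.image_width_px,
                            image_height_px=camera.image_height_px,
                            row_height_px=self.row_height_px,
                            row_top_px=self.row_top_px,
                            area_threshold_px2=self.area_threshold_px2)


class ProtocolBlock(_Strict):
    max_valve_freq_hz: float = Field(10.0, gt=0)
    min_open_s: float = Field(0.1, ge=0)


class DetectorBlock(_Strict):
    input_size: int = Field(640, gt=0, multiple_of=32)
    n_classes: int = Field(1, ge=1)
    se_reduction: int = Field(4, ge=1)
    neck_width: int = Field(48, ge=8)
    conf_threshold: float = Field(0.5, ge=0, le=1)
    nms_threshold: float = Field(0.5, ge=0, le=1)
    epochs: int = Field(50, ge=1)
    batch_size: int = Field(10, ge=1)
    lr_max: float = Field(1e-2, gt=0)
    lr_min: float = Field(5e-5, gt=0)


class SimulatorBlock(_Strict):
    speed_kmh: float = Field(2.0, gt=0)
    fps: float = Field(26.73, gt=0)
    p_detect_frame: float = Field(0.5, ge=0, le=1)
    sigma_loc_mm: float = Field(5.0, ge=0)
    sigma_vib_mm_per_kmh: float = Field(8.0, ge=0)
    valve_latency_ms: float = Field(0.0, ge=0)
    nozzle_spacing_m: float = Field(0.15, gt=0)
    spray_margin_m: float = Field(0.02, ge=0)
    detect_speed_penalty_per_kmh: float = Field(0.0, ge=0)
    row_offset_m: float = 0.0
    density_per_m2: float = Field(1.5, ge=0)
    area_length_m: float = Field(20.0, gt=0)
    area_width_m: float = Field(3.0, gt=0)


class RunConfig(_Strict):
    camera: CameraBlock = Field(default_factory=CameraBlock)
    grille: GrilleBlock = Field(default_factory=GrilleBlock)
    protocol: ProtocolBlock = Field(default_factory=ProtocolBlock)
    detector: DetectorBlock = Field(default_factory=DetectorBlock)
    simulator: SimulatorBlock = Field(default_factory=SimulatorBlock)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Defaults overlaid by the YAML file; unknown keys are errors."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors())
        raise ConfigError(f"invalid configuration: {details}") from exc
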