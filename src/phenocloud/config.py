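"""Run configuration: defaults, YAML loading and schema validation.

The config file is YAML with blocks ``camera``, ``acquisition``,
``measurement``, ``plant`` and ``simulation``; unknown keys anywhere are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import FormatError, InvalidConfigError
from .geometry import DEFAULT_SNAPSHOT_INTERVAL_S, CameraConfig
from .scene import NoiseModel, ObjectSpec, PouDegradation

__all__ = ["RunConfig", "load_config", "default_camera", "config_hash"]

#: POU grid spanned by the survey design (unique values, ascending).
DEFAULT_POU_GRID = (17, 28, 34, 46, 56, 84, 93, 111, 139, 168, 185, 278, 556)


def default_camera() -> CameraConfig:
    """The reference gantry camera (Table 1 style parameters)."""
    return CameraConfig(
        sensor_width_mm=6.17,
        sensor_height_mm=4.55,
        focal_length_mm=4.00,
        image_width_px=5152,
        image_height_px=3864,
        lens_height_mm=1200.0,
    )


@dataclass
class AcquisitionBlock:
    route_spacing_mm: float = 183.0
    forward_speed_mm_s: float = 22.75
    snapshot_interval_s: float = DEFAULT_SNAPSHOT_INTERVAL_S
    downscale_factor: float = 1.0


@dataclass
class MeasurementBlock:
    n_bins: int = 20
    trim_low_bins: int = 5
    trim_high_bins: int = 5
    slice_width_mm: float = 1.0
    center_fraction: float = 0.5
    #: the domed shape needs a tighter center patch for an unbiased apex height
    center_fraction_per_shape: dict = field(
        default_factory=lambda: {"mushroom": 0.15}
    )
    bottom_percentile: float = 1.0
    min_points_per_slice: int = 5


@dataclass
class PlantBlock:
    n_bins: int = 50
    bed_percentile: float = 1.0


def _default_object_specs() -> dict:
    return {
        "O1": ObjectSpec("cuboid", (120.0, 100.0, 150.0)),
        "O2": ObjectSpec("cylinder", (50.0, 150.0)),
        "O3": ObjectSpec("mushroom", (25.0, 90.0, 60.0)),
    }


@dataclass
class SimulationBlock:
    object_specs: dict = field(default_factory=_default_object_specs)
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(density_pts_per_mm2=0.8))
    degradation: PouDegradation = field(default_factory=PouDegradation)
    pou_values: tuple = DEFAULT_POU_GRID
    replicates: int = 3
    bed_margin_mm: float = 10.0


@dataclass
class RunConfig:
    camera: CameraConfig = field(default_factory=default_camera)
    acquisition: AcquisitionBlock = field(default_factory=AcquisitionBlock)
    measurement: MeasurementBlock = field(default_factory=MeasurementBlock)
    plant: PlantBlock = field(default_factory=PlantBlock)
    simulation: SimulationBlock = field(default_factory=SimulationBlock)


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise FormatError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise FormatError(f"{context}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise InvalidConfigError(f"{context}: {exc}") from exc


def _build_object_specs(data, context: str) -> dict:
    specs = {}
    for name, entry in data.items():
        if not isinstance(entry, dict) or "shape" not in entry or "dims" not in entry:
            raise FormatError(f"{context}.{name}: needs 'shape' and 'dims'")
        specs[name] = ObjectSpec(
            entry["shape"], tuple(entry["dims"]), tuple(entry.get("center", (0.0, 0.0)))
        )
    return specs


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file; missing blocks keep defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    known = {"camera", "acquisition", "measurement", "plant", "simulation"}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown block(s) {sorted(unknown)}")

    cfg = RunConfig()
    if "camera" in data:
        cfg.camera = _build(CameraConfig, data["camera"], "camera")
    if "acquisition" in data:
        cfg.acquisition = _build(AcquisitionBlock, data["acquisition"], "acquisition")
    if "measurement" in data:
        cfg.measurement = _build(MeasurementBlock, data["measurement"], "measurement")
    if "plant" in data:
        cfg.plant = _build(PlantBlock, data["plant"], "plant")
    if "simulation" in data:
        sim = dict(data["simulation"])
        if "object_specs" in sim:
            sim["object_specs"] = _build_object_specs(sim["object_specs"], "simulation.object_specs")
        if "noise" in sim:
            sim["noise"] = _build(NoiseModel, sim["noise"], "simulation.noise")
        if "degradation" in sim:
            sim["degradation"] = _build(PouDegradation, sim["degradation"], "simulation.degradation")
        if "pou_values" in sim:
            sim["pou_values"] = tuple(sim["pou_values"])
        cfg.simulation = _build(SimulationBlock, sim, "simulation")
    return cfg


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a config, for reproducibility logging."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    blob = json.dumps(encode(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
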