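"""Acquisition geometry: field of view, image overlap, spatial resolution
and the combined POU (power of unit) metric, plus the inverse planner that
turns target overlaps into gantry settings.

All lengths are millimetres, speeds mm/s, overlaps percent.  Computations
keep full floating-point precision; only the ``report_*`` helpers round the
way survey tables conventionally print (overlaps and POU to integers, SR to
two decimals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .exceptions import InvalidConfigError, NegativeOverlapError

__all__ = [
    "CameraConfig",
    "FieldOfView",
    "AcquisitionSetting",
    "compute_fov",
    "side_overlap",
    "forward_overlap",
    "compute_sr",
    "compute_pou",
    "plan_acquisition",
    "evaluate_acquisition",
    "report_percent",
    "report_pou",
    "report_sr",
    "overlap_table",
    "pou_table",
]

#: Snapshot interval (s) used for design computations.
DEFAULT_SNAPSHOT_INTERVAL_S = 3.0


@dataclass(frozen=True)
class CameraConfig:
    """Sensor, optics and mounting parameters of the nadir camera."""

    sensor_width_mm: float
    sensor_height_mm: float
    focal_length_mm: float
    image_width_px: int
    image_height_px: int
    lens_height_mm: float

    def __post_init__(self) -> None:
        for name in (
            "sensor_width_mm",
            "sensor_height_mm",
            "focal_length_mm",
            "image_width_px",
            "image_height_px",
            "lens_height_mm",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise InvalidConfigError(f"{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class FieldOfView:
    """Ground footprint of one image: long edge (width) and short edge (height)."""

    fov_w_mm: float
    fov_h_mm: float


@dataclass(frozen=True)
class AcquisitionSetting:
    """A survey setting together with its derived overlap/resolution metrics."""

    route_spacing_mm: float
    forward_speed_mm_s: float
    snapshot_interval_s: float
    downscale_factor: float
    forward_step_mm: float
    side_overlap_pct: float
    forward_overlap_pct: float
    sr_px_per_mm: float
    pou_px_per_mm: float


def compute_fov(camera: CameraConfig) -> FieldOfView:
    """Ground field of view from the pinhole similar-triangles relation.

    width = sensor_width * lens_height / focal_length, same for height.
    """
    scale = camera.lens_height_mm / camera.focal_length_mm
    return FieldOfView(camera.sensor_width_mm * scale, camera.sensor_height_mm * scale)


def side_overlap(route_spacing_mm: float, fov_w_mm: float) -> float:
    """Percent overlap of two images on neighbouring routes."""
    if fov_w_mm <= 0:
        raise InvalidConfigError("fov_w_mm must be positive")
    if route_spacing_mm < 0:
        raise InvalidConfigError("route spacing must be non-negative")
    if route_spacing_mm > fov_w_mm:
        raise NegativeOverlapError(
            f"route spacing {route_spacing_mm} mm exceeds FOV width {fov_w_mm} mm"
        )
    return (fov_w_mm - route_spacing_mm) / fov_w_mm * 100.0


def forward_overlap(
    forward_speed_mm_s: float, snapshot_interval_s: float, fov_h_mm: float
) -> float:
    """Percent overlap of two consecutive images along a route.

    The along-route step is speed x snapshot interval.
    """
    if snapshot_interval_s <= 0:
        raise InvalidConfigError("snapshot interval must be positive")
    if forward_speed_mm_s < 0:
        raise InvalidConfigError("forward speed must be non-negative")
    step = forward_speed_mm_s * snapshot_interval_s
    if fov_h_mm <= 0:
        raise InvalidConfigError("fov_h_mm must be positive")
    if step > fov_h_mm:
        raise NegativeOverlapError(
            f"forward step {step} mm exceeds FOV height {fov_h_mm} mm"
        )
    return (fov_h_mm - step) / fov_h_mm * 100.0


def compute_sr(image_width_px: float, fov_w_mm: float) -> float:
    """Spatial resolution in pixels per mm of ground at bed level."""
    if image_width_px <= 0 or fov_w_mm <= 0:
        raise InvalidConfigError("image width and FOV width must be positive")
    return image_width_px / fov_w_mm


def compute_pou(
    sr_px_per_mm: float, side_overlap_pct: float, forward_overlap_pct: float
) -> float:
    """POU = SR * 1e4 / ((100 - Ox)(100 - Oy)).

    Combines spatial resolution with side and forward overlap into a single
    shared-pixel-density metric; higher POU means denser, more complete
    reconstructions.
    """
    if sr_px_per_mm <= 0:
        raise InvalidConfigError("SR must be positive")
    for name, o in (("side", side_overlap_pct), ("forward", forward_overlap_pct)):
        if o < 0:
            raise InvalidConfigError(f"{name} overlap must be non-negative, got {o}")
        if o >= 100:
            raise InvalidConfigError(
                f"{name} overlap of {o}% gives an unbounded POU; overlaps must be < 100%"
            )
    return sr_px_per_mm * 1.0e4 / ((100.0 - side_overlap_pct) * (100.0 - forward_overlap_pct))


def evaluate_acquisition(
    camera: CameraConfig,
    route_spacing_mm: float,
    forward_speed_mm_s: float,
    snapshot_interval_s: float = DEFAULT_SNAPSHOT_INTERVAL_S,
    downscale_factor: float = 1.0,
) -> AcquisitionSetting:
    """Derive overlaps, SR and POU for a concrete gantry setting.

    ``downscale_factor`` divides the image width before the SR computation,
    modelling post-hoc image downscaling (no resampling is performed).
    """
    if downscale_factor < 1:
        raise InvalidConfigError("downscale factor must be >= 1")
    fov = compute_fov(camera)
    o_x = side_overlap(route_spacing_mm, fov.fov_w_mm)
    o_y = forward_overlap(forward_speed_mm_s, snapshot_interval_s, fov.fov_h_mm)
    sr = compute_sr(camera.image_width_px / downscale_factor, fov.fov_w_mm)
    return AcquisitionSetting(
        route_spacing_mm=route_spacing_mm,
        forward_speed_mm_s=forward_speed_mm_s,
        snapshot_interval_s=snapshot_interval_s,
        downscale_factor=downscale_factor,
        forward_step_mm=forward_speed_mm_s * snapshot_interval_s,
        side_overlap_pct=o_x,
        forward_overlap_pct=o_y,
        sr_px_per_mm=sr,
        pou_px_per_mm=compute_pou(sr, o_x, o_y),
    )


def plan_acquisition(
    camera: CameraConfig,
    target_side_overlap_pct: float,
    target_forward_overlap_pct: float,
    snapshot_interval_s: float = DEFAULT_SNAPSHOT_INTERVAL_S,
    downscale_factor: float = 1.0,
) -> AcquisitionSetting:
    """Invert the overlap relations: target overlaps -> route spacing and speed."""
    for name, o in (
        ("side", target_side_overlap_pct),
        ("forward", target_forward_overlap_pct),
    ):
        if not 0 <= o < 100:
            raise InvalidConfigError(f"target {name} overlap must be in [0, 100), got {o}")
    if snapshot_interval_s <= 0:
        raise InvalidConfigError("snapshot interval must be positive")
    fov = compute_fov(camera)
    route_spacing = fov.fov_w_mm * (1.0 - target_side_overlap_pct / 100.0)
    speed = fov.fov_h_mm * (1.0 - target_forward_overlap_pct / 100.0) / snapshot_interval_s
    return evaluate_acquisition(
        camera, route_spacing, speed, snapshot_interval_s, downscale_factor
    )


def report_percent(value: float) -> int:
    """Round an overlap percentage to the nearest integer (half up)."""
    return int(math.floor(value + 0.5))


def report_pou(value: float) -> int:
    """Round a POU to the nearest integer (half up), as survey tables print."""
    return int(math.floor(value + 0.5))


def report_sr(value: float) -> float:
    """Round an SR to two decimals."""
    return round(value, 2)


def overlap_table(
    camera: CameraConfig,
    route_spacings_mm: list[float],
    forward_speeds_mm_s: list[float],
    snapshot_interval_s: float = DEFAULT_SNAPSHOT_INTERVAL_S,
) -> pd.DataFrame:
    """Cross all route spacings with all speeds and report integer overlaps."""
    rows = []
    for lx in route_spacings_mm:
        for speed in forward_speeds_mm_s:
            setting = evaluate_acquisition(camera, lx, speed, snapshot_interval_s)
            rows.append(
                {
                    "route_spacing_mm": lx,
                    "side_overlap_pct": report_percent(setting.side_overlap_pct),
                    "forward_speed_mm_s": speed,
                    "forward_overlap_pct": report_percent(setting.forward_overlap_pct),
                }
            )
    return pd.DataFrame(rows)


def pou_table(
    sr_values: list[float],
    side_overlaps_pct: list[float],
    forward_overlaps_pct: list[float],
) -> pd.DataFrame:
    """POU for every (SR, side overlap, forward overlap) combination."""
    rows = []
    for sr in sr_values:
        for ox in side_overlaps_pct:
            for oy in forward_overlaps_pct:
                rows.append(
                    {
                        "sr_px_per_mm": report_sr(sr),
                        "side_overlap_pct": ox,
                        "forward_overlap_pct": oy,
                        "pou_px_per_mm": report_pou(compute_pou(sr, ox, oy)),
                    }
                )
    return pd.DataFrame(rows)
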