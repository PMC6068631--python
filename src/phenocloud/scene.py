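"""Synthetic dense-cloud generator.

Stands in for the greenhouse imagery and SfM reconstructions: seeded
surface-sampled clouds of the three calibration shapes (cuboid, cylinder,
mushroom) and of green plants on a dark bed, with a POU-driven degradation
model (density loss, side-surface dropout, jitter) whose induced dimension
errors follow a power law in POU.

Every generated point carries a ground-truth surface label so downstream
estimators can be tested against the generator itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np

from .cloud import PointCloud
from .exceptions import InvalidConfigError

__all__ = [
    "ObjectSpec",
    "NoiseModel",
    "PouDegradation",
    "PlantSpec",
    "make_object_cloud",
    "degrade_for_pou",
    "make_plant_cloud",
    "make_error_dataset",
    "surface_area",
]

SHAPES = ("cuboid", "cylinder", "mushroom")


@dataclass(frozen=True)
class ObjectSpec:
    """Geometry of one calibration object sitting on the bed plane (z = 0).

    Dimensions in mm.  ``dims`` is shape-dependent:
      cuboid   — (width_x, depth_y, height_z)
      cylinder — (radius, height)
      mushroom — (stem_radius, stem_height, cap_radius); hemispherical cap,
                 total height = stem_height + cap_radius
    """

    shape: str
    dims: tuple[float, ...]
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise InvalidConfigError(
                f"unknown shape {self.shape!r}; expected one of {SHAPES}"
            )
        n_expected = {"cuboid": 3, "cylinder": 2, "mushroom": 3}[self.shape]
        if len(self.dims) != n_expected:
            raise InvalidConfigError(
                f"{self.shape} takes {n_expected} dimensions, got {len(self.dims)}"
            )
        if any(d <= 0 for d in self.dims):
            raise InvalidConfigError(f"dimensions must be positive, got {self.dims}")
        if self.shape == "mushroom" and self.dims[2] < self.dims[0]:
            raise InvalidConfigError("mushroom cap radius must be >= stem radius")

    @property
    def true_dims(self) -> tuple[float, float, float]:
        """Ground-truth extent in x, y, z."""
        if self.shape == "cuboid":
            return self.dims
        if self.shape == "cylinder":
            r, h = self.dims
            return (2 * r, 2 * r, h)
        stem_r, stem_h, cap_r = self.dims
        return (2 * cap_r, 2 * cap_r, stem_h + cap_r)


@dataclass(frozen=True)
class NoiseModel:
    """Reconstruction imperfections applied to a sampled surface.

    ``lateral_dropout_frac`` removes that fraction of side-surface points
    (Bernoulli per point), mimicking the incomplete object flanks seen in
    low-overlap reconstructions.  Outliers are displaced along the local
    surface normal by ``outlier_offset_mm``, mimicking floating noise.
    """

    density_pts_per_mm2: float = 1.0
    jitter_sd_mm: float = 0.0
    lateral_dropout_frac: float = 0.0
    outlier_rate: float = 0.0
    outlier_offset_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.density_pts_per_mm2 <= 0:
            raise InvalidConfigError("density must be positive")
        if self.jitter_sd_mm < 0:
            raise InvalidConfigError("jitter sd must be >= 0")
        for name in ("lateral_dropout_frac", "outlier_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class PouDegradation:
    """Maps a POU value to (density scale, lateral dropout, jitter sd).

    Each component is a clamped power law anchored at ``pou_ref``:
      density scale  ~ (pou / pou_ref) ** density_exponent   (increasing)
      dropout        ~ dropout_at_ref * (pou_ref / pou) ** dropout_exponent
      jitter sd [mm] ~ jitter_at_ref_mm * (pou_ref / pou) ** jitter_exponent

    The defaults are calibration constants chosen so the default pipeline
    produces x/y errors in the observed 0-10 mm band for POU >= 150 and
    monotonically growing errors as POU falls; they are configuration, not
    physical claims.
    """

    pou_ref: float = 278.0
    pou_min: float = 10.0
    pou_max: float = 600.0
    density_exponent: float = 0.35
    dropout_at_ref: float = 0.15
    dropout_exponent: float = 0.5
    dropout_max: float = 0.9
    jitter_at_ref_mm: float = 1.2
    jitter_exponent: float = 0.55

    def _clamp(self, pou: float) -> float:
        if pou <= 0:
            raise InvalidConfigError("POU must be positive")
        if pou < self.pou_min or pou > self.pou_max:
            warnings.warn(
                f"POU {pou} outside calibrated range "
                f"[{self.pou_min}, {self.pou_max}]; clamping",
                stacklevel=3,
            )
        return float(np.clip(pou, self.pou_min, self.pou_max))

    def density_scale(self, pou: float) -> float:
        pou = self._clamp(pou)
        return float(min(1.0, (pou / self.pou_ref) ** self.density_exponent))

    def lateral_dropout_frac(self, pou: float) -> float:
        pou = self._clamp(pou)
        return float(
            np.clip(
                self.dropout_at_ref * (self.pou_ref / pou) ** self.dropout_exponent,
                0.0,
                self.dropout_max,
            )
        )

    def jitter_sd_mm(self, pou: float) -> float:
        pou = self._clamp(pou)
        return self.jitter_at_ref_mm * (self.pou_ref / pou) ** self.jitter_exponent


@dataclass(frozen=True)
class PlantSpec:
    """A single potted plant on a dark bed.

    Canopy points are green-dominant by construction (G > R and B <= R, so
    the greenness index is strictly positive before any noise); bed points
    are exact gray (R = G = B, index exactly zero).
    """

    plant_height_mm: float = 300.0
    canopy_radius_mm: float = 100.0
    canopy_depth_frac: float = 0.55
    stem_radius_mm: float = 5.0
    bed_half_width_mm: float = 220.0
    n_canopy_points: int = 4000
    n_stem_points: int = 400
    n_bed_points: int = 4000
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.plant_height_mm <= 0:
            raise InvalidConfigError("plant height must be positive")
        if not 0 < self.canopy_depth_frac < 1:
            raise InvalidConfigError("canopy_depth_frac must be in (0, 1)")


# ---------------------------------------------------------------------------
# surface sampling


def surface_area(spec: ObjectSpec) -> float:
    """Camera-visible surface area (top + lateral faces) in mm^2."""
    if spec.shape == "cuboid":
        w, d, h = spec.dims
        return w * d + 2 * h * (w + d)
    if spec.shape == "cylinder":
        r, h = spec.dims
        return np.pi * r * r + 2 * np.pi * r * h
    stem_r, stem_h, cap_r = spec.dims
    # hemisphere cap + stem wall + exposed cap underside annulus is hidden
    return 2 * np.pi * cap_r * cap_r + 2 * np.pi * stem_r * stem_h


def _sample_cuboid(spec: ObjectSpec, rng: np.random.Generator, density: float):
    w, d, h = spec.dims
    areas = np.array([w * d, d * h, d * h, w * h, w * h])
    counts = rng.poisson(areas * density)
    parts, labels, normals = [], [], []
    # top
    n = counts[0]
    top = np.column_stack(
        [rng.uniform(0, w, n), rng.uniform(0, d, n), np.full(n, h)]
    )
    parts.append(top)
    labels.append(np.full(n, "top"))
    normals.append(np.tile([0.0, 0.0, 1.0], (n, 1)))
    # four walls: (fixed axis, value, normal)
    walls = [
        (0, 0.0, [-1.0, 0.0, 0.0]),
        (0, w, [1.0, 0.0, 0.0]),
        (1, 0.0, [0.0, -1.0, 0.0]),
        (1, d, [0.0, 1.0, 0.0]),
    ]
    for (axis, value, normal), n in zip(walls, counts[1:]):
        pts = np.empty((n, 3))
        pts[:, axis] = value
        pts[:, 1 - axis] = rng.uniform(0, (d if axis == 0 else w), n)
        pts[:, 2] = rng.uniform(0, h, n)
        parts.append(pts)
        labels.append(np.full(n, "lateral"))
        normals.append(np.tile(normal, (n, 1)))
    xyz = np.vstack(parts)
    xyz[:, 0] -= w / 2.0
    xyz[:, 1] -= d / 2.0
    return xyz, np.concatenate(labels), np.vstack(normals)


def _sample_cylinder(spec: ObjectSpec, rng: np.random.Generator, density: float):
    r, h = spec.dims
    n_top = rng.poisson(np.pi * r * r * density)
    n_lat = rng.poisson(2 * np.pi * r * h * density)
    # top disc: uniform via sqrt radius
    rho = r * np.sqrt(rng.uniform(0, 1, n_top))
    theta = rng.uniform(0, 2 * np.pi, n_top)
    top = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), np.full(n_top, h)])
    phi = rng.uniform(0, 2 * np.pi, n_lat)
    lat = np.column_stack(
        [r * np.cos(phi), r * np.sin(phi), rng.uniform(0, h, n_lat)]
    )
    xyz = np.vstack([top, lat])
    labels = np.concatenate([np.full(n_top, "top"), np.full(n_lat, "lateral")])
    normals = np.vstack(
        [
            np.tile([0.0, 0.0, 1.0], (n_top, 1)),
            np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n_lat)]),
        ]
    )
    return xyz, labels, normals


def _sample_mushroom(spec: ObjectSpec, rng: np.random.Generator, density: float):
    stem_r, stem_h, cap_r = spec.dims
    n_cap = rng.poisson(2 * np.pi * cap_r * cap_r * density)
    n_stem = rng.poisson(2 * np.pi * stem_r * stem_h * density)
    # hemisphere: uniform via z ~ U(0, 1) on the unit upper hemisphere
    u = rng.uniform(0, 1, n_cap)
    theta = rng.uniform(0, 2 * np.pi, n_cap)
    s = np.sqrt(1 - u * u)
    cap_dir = np.column_stack([s * np.cos(theta), s * np.sin(theta), u])
    cap = cap_dir * cap_r
    cap[:, 2] += stem_h
    phi = rng.uniform(0, 2 * np.pi, n_stem)
    stem = np.column_stack(
        [stem_r * np.cos(phi), stem_r * np.sin(phi), rng.uniform(0, stem_h, n_stem)]
    )
    xyz = np.vstack([cap, stem])
    # cap counts as "top", stem wall as "lateral"
    labels = np.concatenate([np.full(n_cap, "top"), np.full(n_stem, "lateral")])
    normals = np.vstack(
        [cap_dir, np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n_stem)])]
    )
    return xyz, labels, normals


_SAMPLERS = {
    "cuboid": _sample_cuboid,
    "cylinder": _sample_cylinder,
    "mushroom": _sample_mushroom,
}


def _object_color(rng: np.random.Generator, n: int) -> np.ndarray:
    """Light gray foam: exact R = G = B so the greenness index is zero."""
    v = rng.integers(170, 231, n)
    return np.column_stack([v, v, v]).astype(np.uint8)


def _bed_color(rng: np.random.Generator, n: int) -> np.ndarray:
    """Dark fiber sheet: exact gray."""
    v = rng.integers(20, 61, n)
    return np.column_stack([v, v, v]).astype(np.uint8)


def make_object_cloud(
    spec: ObjectSpec,
    noise: NoiseModel | None = None,
    seed: int = 0,
    bed_margin_mm: float = 10.0,
) -> PointCloud:
    """Sample the camera-visible surface of one calibration object.

    The object sits with its base at z = 0, centered at ``spec.center``.
    A ``bed_margin_mm`` ring of bed points at z = 0 around the object
    footprint is included (label ``bed``), matching what a crop rectangle
    around a real object contains.  Jitter, lateral dropout and outliers
    are applied in that order; deterministic given ``seed``.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    xyz, labels, normals = _SAMPLERS[spec.shape](spec, rng, noise.density_pts_per_mm2)

    if bed_margin_mm > 0:
        dim_x, dim_y, _ = spec.true_dims
        half_x, half_y = dim_x / 2 + bed_margin_mm, dim_y / 2 + bed_margin_mm
        rect_area = 4 * half_x * half_y
        n_bed = rng.poisson(rect_area * noise.density_pts_per_mm2)
        bx = rng.uniform(-half_x, half_x, n_bed)
        by = rng.uniform(-half_y, half_y, n_bed)
        outside = ~_inside_footprint(spec, bx, by)
        bed = np.column_stack([bx[outside], by[outside], np.zeros(outside.sum())])
        xyz = np.vstack([xyz, bed])
        labels = np.concatenate([labels, np.full(len(bed), "bed")])
        normals = np.vstack([normals, np.tile([0.0, 0.0, 1.0], (len(bed), 1))])

    xyz, labels, normals = _apply_dropout(
        xyz, labels, normals, noise.lateral_dropout_frac, rng
    )
    if noise.jitter_sd_mm > 0:
        xyz = xyz + rng.normal(0.0, noise.jitter_sd_mm, xyz.shape)
    xyz = _apply_outliers(xyz, normals, noise, rng)
    xyz[:, 0] += spec.center[0]
    xyz[:, 1] += spec.center[1]

    n = len(xyz)
    rgb = np.where(
        (labels == "bed")[:, None], _bed_color(rng, n), _object_color(rng, n)
    ).astype(np.uint8)
    return PointCloud(xyz, rgb, labels)


def _footprint_area(spec: ObjectSpec) -> float:
    if spec.shape == "cuboid":
        return spec.dims[0] * spec.dims[1]
    r = spec.dims[0] if spec.shape == "cylinder" else spec.dims[2]
    return np.pi * r * r


def _inside_footprint(spec: ObjectSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if spec.shape == "cuboid":
        w, d, _ = spec.dims
        return (np.abs(x) <= w / 2) & (np.abs(y) <= d / 2)
    r = spec.dims[0] if spec.shape == "cylinder" else spec.dims[2]
    return x * x + y * y <= r * r


def _apply_dropout(xyz, labels, normals, frac, rng):
    if frac <= 0:
        return xyz, labels, normals
    drop = (labels == "lateral") & (rng.uniform(size=len(xyz)) < frac)
    keep = ~drop
    return xyz[keep], labels[keep], normals[keep]


def _apply_outliers(xyz, normals, noise: NoiseModel, rng):
    if noise.outlier_rate <= 0:
        return xyz
    mask = rng.uniform(size=len(xyz)) < noise.outlier_rate
    out = xyz.copy()
    out[mask] += normals[mask] * noise.outlier_offset_mm
    return out


def degrade_for_pou(
    cloud: PointCloud,
    pou: float,
    degradation: PouDegradation | None = None,
    seed: int = 0,
) -> PointCloud:
    """Degrade a clean cloud to emulate a reconstruction at the given POU.

    Thins all points to the POU-mapped density scale, removes the mapped
    fraction of lateral points, then adds the mapped jitter.  Deterministic
    given ``seed``.
    """
    degradation = degradation or PouDegradation()
    rng = np.random.default_rng(seed)
    scale = degradation.density_scale(pou)
    keep = rng.uniform(size=len(cloud)) < scale
    if cloud.labels is not None:
        frac = degradation.lateral_dropout_frac(pou)
        if frac > 0:
            drop = (cloud.labels == "lateral") & (rng.uniform(size=len(cloud)) < frac)
            keep &= ~drop
    out = cloud.select(keep)
    sd = degradation.jitter_sd_mm(pou)
    if sd > 0:
        out = PointCloud(out.xyz + rng.normal(0.0, sd, out.xyz.shape), out.rgb, out.labels)
    return out


# ---------------------------------------------------------------------------
# plants


def _canopy_colors(rng: np.random.Generator, n: int) -> np.ndarray:
    r = rng.integers(30, 91, n)
    g = np.minimum(r + rng.integers(80, 131, n), 255)
    b = rng.integers(10, 41, n)
    b = np.minimum(b, r)  # B <= R keeps the greenness index strictly positive
    return np.column_stack([r, g, b]).astype(np.uint8)


def make_plant_cloud(spec: PlantSpec, seed: int = 0) -> PointCloud:
    """One green plant (canopy shell + stem) on a dark bed at z = 0.

    The highest canopy point is rescaled to sit exactly at
    ``plant_height_mm`` before noise, so the noise-free plant has an exact
    ground-truth height.  Labels: ``plant`` / ``background``.
    """
    rng = np.random.default_rng(seed)
    h, r_c = spec.plant_height_mm, spec.canopy_radius_mm
    z_lo = h * (1.0 - spec.canopy_depth_frac)

    # canopy: upper hemispheroid shell with radial thickness
    n = spec.n_canopy_points
    u = rng.uniform(0, 1, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - u * u)
    shell = rng.uniform(0.7, 1.0, n)[:, None]
    dirs = np.column_stack([s * np.cos(theta), s * np.sin(theta), u])
    canopy = dirs * shell
    canopy[:, 0] *= r_c
    canopy[:, 1] *= r_c
    canopy[:, 2] = z_lo + canopy[:, 2] * (h - z_lo)
    top = canopy[:, 2].max()
    if top > z_lo:  # rescale so the true max is exactly the spec height
        canopy[:, 2] = z_lo + (canopy[:, 2] - z_lo) * (h - z_lo) / (top - z_lo)

    phi = rng.uniform(0, 2 * np.pi, spec.n_stem_points)
    stem = np.column_stack(
        [
            spec.stem_radius_mm * np.cos(phi),
            spec.stem_radius_mm * np.sin(phi),
            rng.uniform(0, z_lo, spec.n_stem_points),
        ]
    )

    hw = spec.bed_half_width_mm
    bed = np.column_stack(
        [
            rng.uniform(-hw, hw, spec.n_bed_points),
            rng.uniform(-hw, hw, spec.n_bed_points),
            np.zeros(spec.n_bed_points),
        ]
    )

    xyz = np.vstack([canopy, stem, bed])
    n_plant = len(canopy) + len(stem)
    labels = np.concatenate([np.full(n_plant, "plant"), np.full(len(bed), "background")])
    rgb = np.vstack([_canopy_colors(rng, n_plant), _bed_color(rng, len(bed))])

    if spec.noise.jitter_sd_mm > 0:
        xyz = xyz + rng.normal(0.0, spec.noise.jitter_sd_mm, xyz.shape)
    if spec.noise.outlier_rate > 0:
        mask = rng.uniform(size=len(xyz)) < spec.noise.outlier_rate
        xyz[mask, 2] += spec.noise.outlier_offset_mm
    return PointCloud(xyz, rgb, labels)


# ---------------------------------------------------------------------------
# synthetic error datasets


def make_error_dataset(
    a: float,
    b: float,
    noise_sd_log: float,
    pou_values,
    seed: int = 0,
) -> np.ndarray:
    """Errors following err_i = a * POU_i**b * exp(eps_i), eps ~ N(0, sd^2).

    Returns a structured array with fields ``pou`` and ``abs_error_mm``.
    """
    if a <= 0:
        raise InvalidConfigError("coefficient a must be positive")
    pou = np.asarray(pou_values, dtype=float)
    if np.any(pou <= 0):
        raise InvalidConfigError("all POU values must be positive")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd_log, pou.shape) if noise_sd_log > 0 else 0.0
    err = a * pou ** b * np.exp(eps)
    out = np.empty(pou.shape[0], dtype=[("pou", float), ("abs_error_mm", float)])
    out["pou"] = pou
    out["abs_error_mm"] = err
    return out
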