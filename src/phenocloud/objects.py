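"""Dimension extraction for calibration objects.

Pipeline: crop a rectangle around the object, zero the bottom against a
robust low z percentile, take the height as a trimmed-histogram mean of the
z values in the center of the footprint, and take the x/y dimensions as
trimmed-histogram means of per-z-slice extents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cloud import PointCloud
from .exceptions import EmptySegmentError, InvalidConfigError

__all__ = [
    "RectRegion",
    "TrimSpec",
    "Measurement",
    "crop_rectangle",
    "zero_bottom",
    "trimmed_histogram_mean",
    "measure_height",
    "slice_extents",
    "measure_xy",
    "measure_object",
]

_DEGENERATE_RANGE = 1e-9


@dataclass(frozen=True)
class RectRegion:
    """Axis-aligned crop rectangle on the bed plane, bounds inclusive."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidConfigError(
                f"degenerate region {self.x_min, self.x_max, self.y_min, self.y_max}"
            )


@dataclass(frozen=True)
class TrimSpec:
    """Histogram trim: drop the lowest/highest-edge bins of an equal-width
    histogram before averaging, discarding extreme values and noise."""

    n_bins: int = 20
    trim_low_bins: int = 5
    trim_high_bins: int = 5

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise InvalidConfigError("n_bins must be >= 1")
        if self.trim_low_bins < 0 or self.trim_high_bins < 0:
            raise InvalidConfigError("trim counts must be >= 0")
        if self.trim_low_bins + self.trim_high_bins >= self.n_bins:
            raise InvalidConfigError("trim_low + trim_high must be < n_bins")


@dataclass(frozen=True)
class Measurement:
    """Measured extents of one object plus retained point counts."""

    dim_x_mm: float
    dim_y_mm: float
    dim_z_mm: float
    n_points_height: int
    n_slices_xy: int


def crop_rectangle(cloud: PointCloud, region: RectRegion) -> PointCloud:
    """Points with x and y inside the region (closed bounds)."""
    x, y = cloud.xyz[:, 0], cloud.xyz[:, 1]
    mask = (
        (x >= region.x_min)
        & (x <= region.x_max)
        & (y >= region.y_min)
        & (y <= region.y_max)
    )
    if not mask.any():
        raise EmptySegmentError(f"no points inside region {region}")
    return cloud.select(mask)


def zero_bottom(cloud: PointCloud, bottom_percentile: float = 1.0) -> PointCloud:
    """Shift z so the (robust) bottom of the cloud sits at zero.

    The bottom is the given lower percentile of z rather than the raw
    minimum, so a few under-floor noise points do not drag the origin down.
    """
    if len(cloud) == 0:
        raise EmptySegmentError("cannot zero an empty cloud")
    if not 0 <= bottom_percentile <= 100:
        raise InvalidConfigError("percentile must be in [0, 100]")
    z_bottom = float(np.percentile(cloud.xyz[:, 2], bottom_percentile))
    return cloud.translated(dz=-z_bottom)


def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bins over [min, max]; a value equal to max falls in the
    top bin."""
    lo, hi = values.min(), values.max()
    idx = np.floor((values - lo) / (hi - lo) * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)


def _trim_mask(values: np.ndarray, trim: TrimSpec) -> np.ndarray:
    """Boolean mask of retained values after histogram-edge trimming.

    Tries the full two-sided trim first; if that would discard the majority
    of the values (tight bulk in an edge bin), retreats to trimming the high
    bins only, then the low bins only, then no trim.  Trimming exists to
    remove extremes and noise, so a candidate that keeps less than half of
    the values is rejected and the bulk is never thrown away in favour of
    outliers.
    """
    idx = _bin_indices(values, trim.n_bins)
    below = idx >= trim.trim_low_bins
    above = idx < trim.n_bins - trim.trim_high_bins
    half = values.size / 2.0
    for keep in (below & above, above, below):
        if keep.sum() >= half:
            return keep
    return np.ones(values.shape, dtype=bool)


def trimmed_histogram_mean(values, trim: TrimSpec = TrimSpec()) -> float:
    """Mean of the values left after dropping those in the lowest- and
    highest-edge histogram bins.

    Falls back to a one-sided trim (and ultimately the plain mean) when the
    two-sided trim would discard everything; returns the plain mean when
    the value range is degenerate.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise EmptySegmentError("trimmed_histogram_mean of empty input")
    if v.max() - v.min() < _DEGENERATE_RANGE:
        return float(v.mean())
    return float(v[_trim_mask(v, trim)].mean())


def _central_mask(cloud: PointCloud, center_fraction: float) -> np.ndarray:
    # robust footprint bounds: a few floating outliers must not drag the
    # "center part" off the object top
    x, y = cloud.xyz[:, 0], cloud.xyz[:, 1]
    x_lo, x_hi = np.percentile(x, [1, 99])
    y_lo, y_hi = np.percentile(y, [1, 99])
    cx, cy = (x_lo + x_hi) / 2, (y_lo + y_hi) / 2
    hx = (x_hi - x_lo) * center_fraction / 2
    hy = (y_hi - y_lo) * center_fraction / 2
    return (np.abs(x - cx) <= hx) & (np.abs(y - cy) <= hy)


def measure_height(
    cloud: PointCloud,
    center_fraction: float = 0.5,
    trim: TrimSpec = TrimSpec(),
) -> tuple[float, int]:
    """Object height from a bottom-zeroed cloud.

    Selects points whose (x, y) fall in the central ``center_fraction`` of
    the footprint bounding box — an automated stand-in for manually picking
    the top center — and returns the trimmed-histogram mean of their z
    together with the number of points used.  With the bottom at zero this
    mean is the height.
    """
    if len(cloud) == 0:
        raise EmptySegmentError("cannot measure an empty cloud")
    if not 0 < center_fraction <= 1:
        raise InvalidConfigError("center_fraction must be in (0, 1]")
    mask = _central_mask(cloud, center_fraction)
    if not mask.any():
        raise EmptySegmentError(
            f"no points in the central {center_fraction:.0%} of the footprint; "
            "try a larger center_fraction"
        )
    z = cloud.xyz[mask, 2]
    return trimmed_histogram_mean(z, trim), int(mask.sum())


def slice_extents(
    cloud: PointCloud,
    slice_width_mm: float = 1.0,
    min_points_per_slice: int = 5,
) -> pd.DataFrame:
    """Per-z-slice x and y extents.

    z is quantized into consecutive slices of ``slice_width_mm`` from the
    cloud bottom; slices with fewer than ``min_points_per_slice`` members
    are skipped.  Returns a DataFrame with columns ``slice_index``,
    ``z_center``, ``n_points``, ``dim_x``, ``dim_y``.
    """
    if slice_width_mm <= 0:
        raise InvalidConfigError("slice width must be positive")
    if len(cloud) == 0:
        raise EmptySegmentError("cannot slice an empty cloud")
    z = cloud.xyz[:, 2]
    z_min = z.min()
    idx = np.floor((z - z_min) / slice_width_mm).astype(int)
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order]
    uniq, starts, counts = np.unique(sorted_idx, return_index=True, return_counts=True)
    rows = []
    xs, ys = cloud.xyz[order, 0], cloud.xyz[order, 1]
    for u, s, c in zip(uniq, starts, counts):
        if c < min_points_per_slice:
            continue
        sl = slice(s, s + c)
        rows.append(
            {
                "slice_index": int(u),
                "z_center": z_min + (u + 0.5) * slice_width_mm,
                "n_points": int(c),
                "dim_x": float(xs[sl].max() - xs[sl].min()),
                "dim_y": float(ys[sl].max() - ys[sl].min()),
            }
        )
    if not rows:
        raise EmptySegmentError(
            f"no slice reached min_points_per_slice={min_points_per_slice}"
        )
    return pd.DataFrame(rows)


def measure_xy(
    cloud: PointCloud,
    slice_width_mm: float = 1.0,
    trim: TrimSpec = TrimSpec(),
    min_points_per_slice: int = 5,
    reduction: str = "trimmed_mean",
) -> tuple[float, float, int]:
    """x and y dimensions as a reduction of the per-slice extents.

    Default reduction is the trimmed-histogram mean (consistent with the
    height estimator); ``max_retained`` takes the maximum over the extents
    that survive trimming instead.
    """
    extents = slice_extents(cloud, slice_width_mm, min_points_per_slice)
    if reduction == "trimmed_mean":
        dim_x = trimmed_histogram_mean(extents["dim_x"].to_numpy(), trim)
        dim_y = trimmed_histogram_mean(extents["dim_y"].to_numpy(), trim)
    elif reduction == "max_retained":
        dim_x = _max_retained(extents["dim_x"].to_numpy(), trim)
        dim_y = _max_retained(extents["dim_y"].to_numpy(), trim)
    else:
        raise InvalidConfigError(f"unknown reduction {reduction!r}")
    return dim_x, dim_y, len(extents)


def _max_retained(v: np.ndarray, trim: TrimSpec) -> float:
    if v.max() - v.min() < _DEGENERATE_RANGE:
        return float(v.max())
    return float(v[_trim_mask(v, trim)].max())


def measure_object(
    cloud: PointCloud,
    slice_width_mm: float = 1.0,
    center_fraction: float = 0.5,
    trim: TrimSpec = TrimSpec(),
    bottom_percentile: float = 1.0,
    min_points_per_slice: int = 5,
    reduction: str = "trimmed_mean",
) -> Measurement:
    """Full per-object measurement: zero bottom, height, then x/y."""
    if len(cloud) == 0:
        raise EmptySegmentError("cannot measure an empty cloud")
    zeroed = zero_bottom(cloud, bottom_percentile)
    dim_z, n_height = measure_height(zeroed, center_fraction, trim)
    dim_x, dim_y, n_slices = measure_xy(
        zeroed, slice_width_mm, trim, min_points_per_slice, reduction
    )
    return Measurement(dim_x, dim_y, dim_z, n_height, n_slices)
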