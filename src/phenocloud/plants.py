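"""Automated plant-height pipeline.

Per plant: compute a per-point triangular greenness index (TGI), split the
points into plant vs background with two-cluster 1-D k-means on the index,
keep the greener cluster intersected with TGI > 0, then read the height
from the highest-edge non-empty bin of a 50-bin z histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cloud import PointCloud
from .exceptions import (
    DegenerateClusterError,
    EmptySegmentError,
    FormatError,
    InvalidConfigError,
    NoPlantError,
)
from .objects import RectRegion, crop_rectangle

__all__ = [
    "PlantSegmentation",
    "tgi",
    "kmeans_two",
    "segment_plant",
    "plant_height",
    "measure_plants",
]


@dataclass(frozen=True)
class PlantSegmentation:
    """Result of plant/background segmentation on one cropped cloud."""

    plant_indices: np.ndarray
    background_indices: np.ndarray
    centers: tuple[float, float]  # (background, plant) in TGI units
    seed: int


def tgi(r, g, b):
    """Triangular greenness index on 8-bit channels.

    TGI = -0.5 * (0.19 * (R - G) - 0.12 * (R - B)).  Positive for green
    vegetation, exactly zero for gray.  Vectorized; channels are validated
    to lie in [0, 255].
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, c in (("R", r), ("G", g), ("B", b)):
        if np.any((c < 0) | (c > 255)):
            raise FormatError(f"{name} channel outside [0, 255]")
    return -0.5 * (0.19 * (r - g) - 0.12 * (r - b))


def _wcss(values: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for k in (0, 1):
        member = values[labels == k]
        if member.size:
            total += float(((member - member.mean()) ** 2).sum())
    return total


def kmeans_two(values, seed: int = 0, max_iter: int = 100, tol: float = 1e-6):
    """Two-cluster k-means on 1-D values; returns (labels, centers).

    In one dimension the optimal 2-means partition is a threshold cut on
    the sorted values, so the global optimum is found exactly by scanning
    all n-1 cuts with prefix sums; a Lloyd pass (which the optimum is a
    fixed point of) then confirms convergence.  Deterministic: no random
    initialization is needed.  Cluster 0 is the lower-center cluster.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise DegenerateClusterError("need at least 2 values to form two clusters")
    if v.max() - v.min() < 1e-12:
        raise DegenerateClusterError("all values identical; cannot split into two clusters")

    order = np.argsort(v, kind="stable")
    s = v[order]
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    n = s.size
    k = np.arange(1, n)  # size of the left cluster
    left_ss = csq[:-1] - csum[:-1] ** 2 / k
    right_sum = csum[-1] - csum[:-1]
    right_sq = csq[-1] - csq[:-1]
    right_ss = right_sq - right_sum ** 2 / (n - k)
    cut = int(np.argmin(left_ss + right_ss))

    labels_sorted = np.zeros(n, dtype=int)
    labels_sorted[cut + 1 :] = 1
    centers = np.array([s[: cut + 1].mean(), s[cut + 1 :].mean()])

    # Lloyd refinement from the optimal cut; converges immediately but keeps
    # the contract that iterations never increase the within-cluster SS.
    for _ in range(max_iter):
        new_labels = (np.abs(s - centers[0]) > np.abs(s - centers[1])).astype(int)
        if new_labels.min() == new_labels.max():  # refuse to empty a cluster
            break
        new_centers = np.array([s[new_labels == 0].mean(), s[new_labels == 1].mean()])
        moved = np.abs(new_centers - centers).max()
        labels_sorted, centers = new_labels, new_centers
        if moved < tol:
            break

    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, (float(centers[0]), float(centers[1]))


def segment_plant(cloud: PointCloud, seed: int = 0, require_kmeans: bool = True,
                  require_positive_tgi: bool = True) -> PlantSegmentation:
    """Classify each point of a colored cloud as plant or background.

    Plant points are those in the higher-TGI k-means cluster AND with
    TGI > 0 (both criteria, conjunctively, by default).  If the index
    values are too uniform to cluster, falls back to the sign rule alone.
    """
    if not cloud.has_color:
        raise FormatError("segment_plant requires a colored cloud")
    if not (require_kmeans or require_positive_tgi):
        raise InvalidConfigError("at least one segmentation criterion must be enabled")
    index = tgi(cloud.rgb[:, 0], cloud.rgb[:, 1], cloud.rgb[:, 2])
    if require_positive_tgi and not np.any(index > 0):
        raise NoPlantError("no point with positive greenness index")

    plant_mask = np.ones(len(cloud), dtype=bool)
    centers = (float(index.min()), float(index.max()))
    if require_kmeans:
        try:
            labels, centers = kmeans_two(index, seed=seed)
            plant_mask = labels == 1  # higher-center cluster
        except DegenerateClusterError:
            if not require_positive_tgi:
                raise
            # uniform index: fall back to the sign rule alone
    if require_positive_tgi:
        plant_mask &= index > 0
    if not plant_mask.any():
        raise NoPlantError("segmentation produced no plant points")
    idx = np.arange(len(cloud))
    return PlantSegmentation(
        plant_indices=idx[plant_mask],
        background_indices=idx[~plant_mask],
        centers=centers,
        seed=seed,
    )


def plant_height(plant_z, n_bins: int = 50) -> float:
    """Height from the highest-edge non-empty bin of an equal-width z
    histogram over the plant points (z already zeroed to the bed plane).

    Returns the mean z of the points in that bin; degenerate z range
    returns the plain mean.
    """
    z = np.asarray(plant_z, dtype=float).ravel()
    if z.size == 0:
        raise EmptySegmentError("plant_height of empty plant set")
    if n_bins < 1:
        raise InvalidConfigError("n_bins must be >= 1")
    lo, hi = z.min(), z.max()
    if hi - lo < 1e-9:
        return float(z.mean())
    idx = np.minimum(np.floor((z - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    top = idx.max()
    return float(z[idx == top].mean())


def measure_plants(
    cloud: PointCloud,
    regions: "dict[str, RectRegion]",
    seed: int = 0,
    n_bins: int = 50,
    bed_percentile: float = 1.0,
) -> pd.DataFrame:
    """Measure every plant in a scene given per-plant crop regions.

    The bed plane under each plant is estimated from the background-classified
    points (low percentile of their z).  Per-plant failures are reported in
    the ``status`` column rather than raised.  Columns: ``plant_id``,
    ``height_mm``, ``n_plant_points``, ``status``.
    """
    rows = []
    for plant_id, region in regions.items():
        row = {"plant_id": plant_id, "height_mm": np.nan, "n_plant_points": 0}
        try:
            crop = crop_rectangle(cloud, region)
            seg = segment_plant(crop, seed=seed)
            z = crop.xyz[:, 2]
            if seg.background_indices.size:
                bed_z = float(np.percentile(z[seg.background_indices], bed_percentile))
            else:
                bed_z = float(z.min())
            plant_z = z[seg.plant_indices] - bed_z
            row["height_mm"] = plant_height(plant_z, n_bins)
            row["n_plant_points"] = int(seg.plant_indices.size)
            row["status"] = "ok"
        except NoPlantError:
            row["status"] = "no_plant"
        except EmptySegmentError:
            row["status"] = "empty_region"
        rows.append(row)
    return pd.DataFrame(rows, columns=["plant_id", "height_mm", "n_plant_points", "status"])
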