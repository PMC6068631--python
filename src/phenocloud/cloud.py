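"""Point cloud container used throughout the pipeline.

Coordinates are millimetres; the z axis points up. Colors, when present,
are 8-bit RGB. Labels are optional per-point ground-truth annotations kept
by the synthetic generators (``top``/``lateral``/``bed`` for objects,
``plant``/``background`` for plant scenes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FormatError

__all__ = ["PointCloud"]


@dataclass
class PointCloud:
    xyz: np.ndarray
    rgb: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise FormatError(f"xyz must be (N, 3), got {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise FormatError("point coordinates must be finite")
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb)
            if self.rgb.shape != self.xyz.shape:
                raise FormatError(
                    f"rgb shape {self.rgb.shape} does not match xyz {self.xyz.shape}"
                )
            self.rgb = self.rgb.astype(np.uint8)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.xyz.shape[0]:
                raise FormatError("labels must have one entry per point")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def has_color(self) -> bool:
        return self.rgb is not None

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Return the sub-cloud given by a boolean mask or index array."""
        return PointCloud(
            self.xyz[mask],
            None if self.rgb is None else self.rgb[mask],
            None if self.labels is None else self.labels[mask],
        )

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "PointCloud":
        return PointCloud(
            self.xyz + np.array([dx, dy, dz], dtype=float),
            self.rgb,
            self.labels,
        )

    @staticmethod
    def concatenate(clouds: "list[PointCloud]") -> "PointCloud":
        if not clouds:
            raise FormatError("cannot concatenate zero clouds")
        xyz = np.vstack([c.xyz for c in clouds])
        rgb = None
        if all(c.rgb is not None for c in clouds):
            rgb = np.vstack([c.rgb for c in clouds])
        labels = None
        if all(c.labels is not None for c in clouds):
            labels = np.concatenate([c.labels for c in clouds])
        return PointCloud(xyz, rgb, labels)
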