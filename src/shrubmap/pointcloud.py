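"""Classified LiDAR point clouds and height normalization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid

__all__ = ["PointCloud", "GROUND", "NON_GROUND", "normalize_heights"]

GROUND = 2       # ASPRS ground class code
NON_GROUND = 1   # ASPRS "unclassified" used for all vegetation/building returns

#: negative normalized heights within this tolerance are clamped to zero
HEIGHT_TOLERANCE = 1e-6


@dataclass
class PointCloud:
    """Discrete LiDAR returns in map coordinates.

    ``height_above_ground`` is absent (None) until :func:`normalize_heights`
    subtracts an interpolated ground elevation.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    classification: np.ndarray            # GROUND / NON_GROUND
    return_number: np.ndarray | None = None
    height_above_ground: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.classification = np.asarray(self.classification, dtype=np.int8)
        n = self.x.size
        if not (self.y.size == self.z.size == self.classification.size == n):
            raise ValueError("x, y, z, classification must have equal length")
        if self.return_number is None:
            self.return_number = np.ones(n, dtype=np.int8)
        else:
            self.return_number = np.asarray(self.return_number, dtype=np.int8)

    def __len__(self) -> int:
        return self.x.size

    @property
    def is_ground(self) -> np.ndarray:
        return self.classification == GROUND

    def subset(self, mask: np.ndarray) -> "PointCloud":
        hag = None if self.height_above_ground is None else self.height_above_ground[mask]
        return PointCloud(self.x[mask], self.y[mask], self.z[mask],
                          self.classification[mask], self.return_number[mask], hag)


def normalize_heights(
    cloud: PointCloud, dem: RasterGrid, boundary_tol: float = 0.01
) -> PointCloud:
    """Attach height above ground = z - bilinear DEM elevation.

    Negative residuals (ground-model noise) are clamped to zero. Points
    outside the DEM extent raise; coordinates within ``boundary_tol``
    metres of the edge (e.g. file round-tripping artifacts) are clamped
    onto it.
    """
    xmin, ymin, xmax, ymax = dem.extent
    x = np.clip(cloud.x, xmin, xmax - 1e-9)
    y = np.clip(cloud.y, ymin + 1e-9, ymax)
    if np.any(np.abs(x - cloud.x) > boundary_tol) or np.any(
        np.abs(y - cloud.y) > boundary_tol
    ):
        raise ValueError("point cloud extends outside the DEM extent")
    ground = dem.sample_bilinear(x, y)
    hag = cloud.z - ground
    hag[hag < 0] = 0.0
    return PointCloud(cloud.x, cloud.y, cloud.z, cloud.classification,
                      cloud.return_number, hag)
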