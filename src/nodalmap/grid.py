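"""Voxel grid for the common template space.

All coordinates are world millimeters in LPS axis order (x: left+,
y: posterior+, z: superior+).  The world position of voxel ``(i, j, k)``
is ``origin + index * spacing`` (voxel-center convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TemplateGrid:
    """Regular 3D voxel grid with a fixed LPS orientation.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    spacing : tuple of float
        Voxel spacing in mm along each axis; strictly positive.
    origin : tuple of float
        World coordinate (mm) of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = field(default="LPS")

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be >= 1 on all axes, got {self.shape}")
        if any(not (s > 0) for s in self.spacing):
            raise ValueError(f"grid spacing must be > 0 on all axes, got {self.spacing}")
        if self.orientation != "LPS":
            raise ValueError("only LPS orientation is supported")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- coordinate transforms -------------------------------------------------

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel indices, shape (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points, shape (..., 3)."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def nearest_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest voxel index for each point plus an in-grid mask.

        Returns
        -------
        idx : (n, 3) int array, clipped to the grid
        inside : (n,) bool array, True where the nearest voxel is within bounds
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite coordinates")
        cont = self.world_to_index(pts)
        idx = np.rint(cont).astype(int)
        shape = np.asarray(self.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        return np.clip(idx, 0, shape - 1), inside

    # -- geometry --------------------------------------------------------------

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def extent_mm(self) -> tuple[tuple[float, float], ...]:
        """Per-axis (min, max) world coordinate of voxel centers."""
        return tuple(
            (o, o + (n - 1) * s)
            for o, s, n in zip(self.origin, self.spacing, self.shape)
        )

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def mirror_x(self, points: np.ndarray) -> np.ndarray:
        """Reflect world points across the grid's mid-sagittal plane."""
        pts = np.asarray(points, dtype=float).copy()
        lo, hi = self.extent_mm[0]
        pts[..., 0] = (lo + hi) - pts[..., 0]
        return pts
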