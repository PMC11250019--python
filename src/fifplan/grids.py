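"""Regular 3D lattices in the DICOM patient coordinate system.

All grids are axis-aligned with the DICOM patient (LPS) axes, use
isotropic or anisotropic voxel spacing in millimetres, 0-based indices,
and place ``origin`` at the *centre* of voxel ``(0, 0, 0)``.  Array axis
``i`` runs along patient x (left), ``j`` along y (posterior), ``k``
along z (superior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid3D", "DensityGrid", "DoseGrid", "StructureMask"]


@dataclass
class Grid3D:
    """A scalar or boolean field sampled on a regular DCS lattice.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    origin : array-like of 3 floats
        DCS coordinates (mm) of the centre of voxel (0, 0, 0).
    spacing : array-like of 3 floats
        Voxel spacing (mm) along x, y, z.  Must be positive.
    """

    data: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"grid data must be 3D, got ndim={self.data.ndim}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def indices_to_coords(self, idx: np.ndarray) -> np.ndarray:
        """DCS coordinates (mm) of voxel centres for an (N, 3) index array."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + idx * self.spacing

    def coords_to_indices(self, pts: np.ndarray) -> np.ndarray:
        """Fractional voxel indices for an (N, 3) array of DCS points."""
        pts = np.asarray(pts, dtype=float)
        return (pts - self.origin) / self.spacing

    def nearest_index(self, point: np.ndarray) -> tuple[int, int, int]:
        """Index of the voxel whose centre is nearest to ``point`` (DCS mm)."""
        idx = np.rint(self.coords_to_indices(np.asarray(point))).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise ValueError(f"point {point} lies outside the grid")
        return tuple(int(i) for i in idx)

    def voxel_centers(self, where: np.ndarray | None = None) -> np.ndarray:
        """(N, 3) DCS coordinates of voxel centres.

        If ``where`` (boolean array of the grid's shape) is given, only
        centres of True voxels are returned, in C order.
        """
        if where is None:
            where = np.ones(self.shape, dtype=bool)
        idx = np.argwhere(where)
        return self.indices_to_coords(idx)

    def same_lattice(self, other: "Grid3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class DensityGrid(Grid3D):
    """Relative electron density (water = 1.0); stands in for the planning CT."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(float)
        if np.any(self.data < 0):
            raise ValueError("densities must be non-negative")


@dataclass
class DoseGrid(Grid3D):
    """Dose in % of prescription; 100 at the isocenter voxel after plan normalization."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(float)


@dataclass
class StructureMask(Grid3D):
    """Boolean structure mask (e.g. BODY, PTV) on the same lattice as its grid."""

    label: str = field(default="")

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    @property
    def volume_mm3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume()
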