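"""Hotspot identification and projection into a binary beam's-eye-view raster.

Hotspots are voxels whose dose strictly exceeds a threshold (in % of
prescription, doses normalized to 100 at the isocenter).  To shape an
MLC block, the 3D hotspot mask is projected through the beam geometry
onto a 2D raster in the isocenter plane: for every hotspot voxel the
eight voxel corners are projected and every raster pixel overlapped by
their bounding rectangle is marked.  The bounding rectangle contains
the convex hull of the projected corners, so the later MLC fit fully
shadows the 3D region (a conservative reading of "completely cover");
no margin is added beyond that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry import BeamGeometry, dcs_to_bev
from .grids import DoseGrid, StructureMask

__all__ = ["BEVMask", "find_hotspots", "project_mask_to_bev"]


@dataclass
class BEVMask:
    """Binary raster in the isocenter plane, axes aligned with (X_BEV, Z_BEV).

    ``data[ix, iz]`` covers the pixel centred at
    ``(x0 + ix * pixel, z0 + iz * pixel)`` with side length ``pixel`` mm.
    """

    data: np.ndarray
    x0: float
    z0: float
    pixel: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("BEV raster must be 2D")
        if self.pixel <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel}")

    @classmethod
    def for_field(
        cls, jaws: tuple[float, float, float, float], pixel: float = 1.0, margin: float = 10.0
    ) -> "BEVMask":
        """Empty raster covering the jaw rectangle (x1, x2, z1, z2) plus a margin."""
        x1, x2, z1, z2 = jaws
        x0 = x1 - margin
        z0 = z1 - margin
        nx = int(np.ceil((x2 + margin - x0) / pixel)) + 1
        nz = int(np.ceil((z2 + margin - z0) / pixel)) + 1
        return cls(np.zeros((nx, nz), dtype=bool), x0, z0, pixel)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def x_centers(self) -> np.ndarray:
        return self.x0 + np.arange(self.shape[0]) * self.pixel

    def z_centers(self) -> np.ndarray:
        return self.z0 + np.arange(self.shape[1]) * self.pixel

    def pixel_index(self, x: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the pixels containing points (x, z)."""
        ix = np.rint((np.asarray(x) - self.x0) / self.pixel).astype(int)
        iz = np.rint((np.asarray(z) - self.z0) / self.pixel).astype(int)
        return ix, iz

    def empty_like(self) -> "BEVMask":
        return BEVMask(np.zeros(self.shape, dtype=bool), self.x0, self.z0, self.pixel)


def find_hotspots(
    dose: DoseGrid, threshold: float, within: StructureMask | None = None
) -> StructureMask:
    """Voxels with dose strictly above ``threshold`` (% of prescription).

    ``within`` restricts the search to a structure (the planner passes
    the PTV, whose dose indices the method controls).
    """
    hot = dose.data > threshold
    if within is not None:
        if not dose.same_lattice(within):
            raise ValueError("dose grid and structure mask are on different lattices")
        hot &= within.data
    return StructureMask(hot, dose.origin, dose.spacing, label="HOTSPOT")


_CORNER_SIGNS = np.array(list(itertools.product((-0.5, 0.5), repeat=3)))  # (8, 3)


def project_mask_to_bev(mask: StructureMask, geom: BeamGeometry, raster: BEVMask) -> BEVMask:
    """Project a 3D voxel mask into a BEV raster (union over voxels).

    Every pixel overlapped by the bounding rectangle of a voxel's eight
    projected corners is marked, so the projection of any point of the
    voxel lies inside the marked region.
    """
    out = raster.empty_like()
    idx = np.argwhere(mask.data)
    if idx.size == 0:
        return out
    centers = mask.indices_to_coords(idx)  # (N, 3)
    corners = centers[:, None, :] + _CORNER_SIGNS[None, :, :] * mask.spacing  # (N, 8, 3)
    bev = dcs_to_bev(corners, geom)  # (N, 8, 2)
    lo = bev.min(axis=1)  # (N, 2)
    hi = bev.max(axis=1)
    px = out.pixel
    # pixel extent [center - px/2, center + px/2); mark pixels intersecting the bbox
    ix_lo = np.floor((lo[:, 0] - out.x0 + px / 2) / px).astype(int)
    ix_hi = np.floor((hi[:, 0] - out.x0 + px / 2) / px).astype(int)
    iz_lo = np.floor((lo[:, 1] - out.z0 + px / 2) / px).astype(int)
    iz_hi = np.floor((hi[:, 1] - out.z0 + px / 2) / px).astype(int)
    nx, nz = out.shape
    ix_lo = np.clip(ix_lo, 0, nx - 1)
    ix_hi = np.clip(ix_hi, 0, nx - 1)
    iz_lo = np.clip(iz_lo, 0, nz - 1)
    iz_hi = np.clip(iz_hi, 0, nz - 1)
    data = out.data
    for a, b, c, d in zip(ix_lo, ix_hi, iz_lo, iz_hi):
        data[a : b + 1, c : d + 1] = True
    return out
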