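"""Synthetic head phantom and the two-opposed-lateral-field original plan.

The phantom is an ellipsoid of water-equivalent density in air whose
lateral (beam-path) thickness shrinks toward the anterior/posterior
extremes, so opposed lateral beams produce the dose hotspots at the
front and back that whole-brain plans show in the frontal and occipital
lobes.  The PTV is the body eroded by 5 mm, keeping surface/buildup
voxels out of the target, in place of a contoured brain.

Default semi-axes (70, 95, 80) mm (lateral / AP / SI) approximate an
adult head; the default 2.5-mm isotropic grid matches the study's dose
grid.  An optional seeded surface perturbation (a few mm) roughens the
ellipsoid to diversify test cases.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import BeamGeometry, dcs_to_bev
from .grids import DensityGrid, StructureMask
from .mlc import MLCAperture, MLCBank
from .plan import Beam, Plan

__all__ = ["make_head_phantom", "make_original_plan"]


def make_head_phantom(
    a: float = 70.0,
    b: float = 95.0,
    c: float = 80.0,
    spacing: float = 2.5,
    seed: int = 0,
    noise_mm: float = 0.0,
    erosion_mm: float = 5.0,
    pad_voxels: int = 2,
) -> tuple[DensityGrid, StructureMask, StructureMask]:
    """Build (density, BODY, PTV) for an ellipsoidal head of semi-axes (a, b, c) mm.

    The grid is centred so that the DCS origin (0, 0, 0) is exactly a
    voxel centre.  ``noise_mm`` adds a smooth seeded radial perturbation
    of that amplitude to the body surface; generation is deterministic
    given (parameters, seed).
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    semi = np.array([a, b, c], dtype=float)
    if np.any(semi <= 2 * spacing):
        raise ValueError("semi-axes must exceed twice the voxel spacing")

    half_n = np.ceil(semi / spacing).astype(int) + pad_voxels
    shape = tuple(2 * half_n + 1)
    origin = -half_n * spacing
    sp = np.full(3, float(spacing))

    coords = [origin[i] + np.arange(shape[i]) * spacing for i in range(3)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    q = np.sqrt((xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2)

    if noise_mm > 0:
        rng = np.random.default_rng(seed)
        coarse = rng.uniform(-1.0, 1.0, size=(5, 5, 5))
        delta = ndimage.zoom(coarse, [s / 5 for s in shape], order=3, grid_mode=True, mode="nearest")
        delta *= noise_mm / max(np.abs(delta).max(), 1e-12)
        # convert the radial offset (mm) into a level-set offset of q
        r_dir = np.sqrt(xx**2 + yy**2 + zz**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            local_radius = np.where(q > 1e-9, r_dir / np.maximum(q, 1e-9), semi.min())
        body = q <= 1.0 + delta / np.maximum(local_radius, spacing)
    else:
        body = q <= 1.0

    density = np.where(body, 1.0, 0.0)
    depth = ndimage.distance_transform_edt(body, sampling=sp)
    ptv = depth > erosion_mm

    density_grid = DensityGrid(density, origin, sp)
    body_mask = StructureMask(body, origin, sp, label="BODY")
    ptv_mask = StructureMask(ptv, origin, sp, label="PTV")
    return density_grid, body_mask, ptv_mask


def make_original_plan(
    body: StructureMask,
    ptv: StructureMask,
    gantry_angles: tuple[float, float] = (90.0, 270.0),
    collimator_deg: float = 0.0,
    sad: float = 1000.0,
    aperture_margin: float = 7.0,
    bank: MLCBank | None = None,
    prescription_gy: float = 30.0,
    fractions: int = 15,
) -> Plan:
    """Two opposed lateral 10-MV fields with rectangular apertures around the PTV.

    The isocenter is placed at the PTV centroid (snapped to the nearest
    voxel centre so dose normalization is exact); each field's jaw
    rectangle encloses the BEV projection of every PTV voxel plus
    ``aperture_margin`` mm; both beams carry equal weight.
    """
    if not ptv.data.any():
        raise ValueError("PTV is empty")
    if bank is None:
        bank = MLCBank.truebeam_hd()

    centroid = ptv.voxel_centers(ptv.data).mean(axis=0)
    iso = tuple(ptv.indices_to_coords(np.array(ptv.nearest_index(centroid))))

    # project PTV voxel corners to size the field
    idx = np.argwhere(ptv.data)
    centers = ptv.indices_to_coords(idx)
    signs = np.array([[sx, sy, sz] for sx in (-0.5, 0.5) for sy in (-0.5, 0.5) for sz in (-0.5, 0.5)])
    corners = (centers[:, None, :] + signs[None, :, :] * ptv.spacing).reshape(-1, 3)

    beams = []
    for i, g in enumerate(gantry_angles, start=1):
        geom = BeamGeometry(iso, g, collimator_deg, sad)
        bev = dcs_to_bev(corners, geom)
        m = aperture_margin
        jaws = (
            round(float(bev[:, 0].min() - m), 1),
            round(float(bev[:, 0].max() + m), 1),
            round(float(bev[:, 1].min() - m), 1),
            round(float(bev[:, 1].max() + m), 1),
        )
        aperture = MLCAperture.open_field(bank, jaws)
        beams.append(Beam(id=f"main{i}", role="main", geometry=geom, aperture=aperture, weight=1.0))
    return Plan(beams, prescription_gy=prescription_gy, fractions=fractions)
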