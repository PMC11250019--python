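"""Simplified divergent-beam photon dose engine.

Each beam deposits, at a voxel centre v inside the body,

    d(v) = w * A(v) * (SAD / r(v))**2 * exp(-mu_eff * l(v))

with r(v) the source-voxel distance, l(v) the radiological path length
from the surface to v along the source ray (trilinear re-sampling of
the density grid along the ray), and A(v) = 1 where the voxel's BEV
projection is open in the aperture, else the MLC/jaw transmission
fraction.  Dose is zero outside the body (density 0).  A plan dose is
the weighted sum of unit-weight beam doses, rescaled so the isocenter
voxel reads 100% of the prescription.

The model is deliberately primary-only (no scatter kernels, buildup or
penumbra): the field-in-field algebra needs a monotone thickness-dose
relation and exact linearity in the beam weights, both of which hold
here by construction.  ``mu_eff`` is an *effective* broad-beam falloff,
not a narrow-beam attenuation coefficient; the 0.0015/mm default makes
a head-sized phantom under 10-MV opposed laterals reach an original-plan
PTV maximum near 107% of prescription, the regime whole-brain plans
show clinically.  0.0035/mm (~3.4%/cm, narrow-beam primary at 10 MV)
produces a much harsher hotspot and is used to exercise the four-sub-
beam escalation path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import dcs_to_bev
from .grids import DensityGrid, DoseGrid
from .plan import Beam, Plan

__all__ = ["EngineConfig", "DoseEngine", "compute_beam_dose", "compute_plan_dose"]


@dataclass(frozen=True)
class EngineConfig:
    """Engine parameters.

    mu_eff : 1/mm
        Effective linear attenuation along the radiological path.
    transmission : dimensionless in [0, 1)
        Fraction of dose transmitted through a closed MLC leaf / jaw.
    inverse_square : bool
        Apply the (SAD/r)^2 divergence factor.
    n_samples : int
        Ray re-sampling points between grid entry and voxel (fixed, so
        results are deterministic).
    """

    mu_eff: float = 0.0015
    transmission: float = 0.015
    inverse_square: bool = True
    n_samples: int = 256

    def __post_init__(self) -> None:
        if self.mu_eff < 0:
            raise ValueError("mu_eff must be >= 0")
        if not 0 <= self.transmission < 1:
            raise ValueError("transmission must be in [0, 1)")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


class DoseEngine:
    """Caches per-geometry ray traces over one density grid.

    Depth and divergence depend only on the beam geometry, not on the
    aperture or weight, so duplicated sub-beams reuse the main beam's
    ray trace and only re-evaluate the cheap aperture factor.
    """

    def __init__(self, density: DensityGrid, cfg: EngineConfig | None = None):
        self.density = density
        self.cfg = cfg or EngineConfig()
        self.body = density.data > 0
        self._idx = np.argwhere(self.body)
        self._centers = density.indices_to_coords(self._idx)
        self._cache: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def variant(self, cfg: EngineConfig) -> "DoseEngine":
        """Engine with different attenuation/transmission sharing this ray-trace cache.

        The trace depends only on geometry and sampling, so variants with
        the same ``n_samples`` reuse it at no cost.
        """
        other = DoseEngine.__new__(DoseEngine)
        other.density = self.density
        other.cfg = cfg
        other.body = self.body
        other._idx = self._idx
        other._centers = self._centers
        other._cache = self._cache if cfg.n_samples == self.cfg.n_samples else {}
        return other

    # -- ray tracing -------------------------------------------------------

    def _trace(self, geom) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(depth, r, bev) arrays over body voxels for one beam geometry."""
        key = (geom.isocenter, geom.gantry_deg, geom.collimator_deg, geom.sad)
        if key in self._cache:
            return self._cache[key]
        src = geom.source_position_dcs()
        vec = self._centers - src
        r = np.linalg.norm(vec, axis=1)
        unit = vec / r[:, None]
        t0 = self._box_entry(src, unit)
        t0 = np.minimum(t0, r)
        depth = self._radiological_depth(src, unit, t0, r)
        bev = dcs_to_bev(self._centers, geom)
        out = (depth, r, bev)
        self._cache[key] = out
        return out

    def _box_entry(self, src: np.ndarray, unit: np.ndarray) -> np.ndarray:
        """Ray parameter at which each ray enters the density bounding box."""
        d = self.density
        lo = d.origin - d.spacing / 2
        hi = d.origin + (np.array(d.shape) - 0.5) * d.spacing
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lo - src) / unit
            t2 = (hi - src) / unit
        tmin = np.minimum(t1, t2)
        tmin = np.where(np.isfinite(tmin), tmin, -np.inf)
        return np.maximum(tmin.max(axis=1), 0.0)

    def _radiological_depth(
        self, src: np.ndarray, unit: np.ndarray, t0: np.ndarray, t1: np.ndarray
    ) -> np.ndarray:
        """Midpoint-rule integral of density along each ray from t0 to t1."""
        m = self.cfg.n_samples
        n = len(t0)
        depth = np.empty(n)
        seg = t1 - t0
        chunk = max(1, int(4_000_000 // m))
        frac = (np.arange(m) + 0.5) / m
        for s in range(0, n, chunk):
            e = min(s + chunk, n)
            ts = t0[s:e, None] + seg[s:e, None] * frac[None, :]
            pos = src[None, None, :] + unit[s:e, None, :] * ts[:, :, None]
            ijk = (pos - self.density.origin) / self.density.spacing
            vals = ndimage.map_coordinates(
                self.density.data,
                ijk.reshape(-1, 3).T,
                order=1,
                mode="constant",
                cval=0.0,
            ).reshape(e - s, m)
            depth[s:e] = vals.mean(axis=1) * seg[s:e]
        return depth

    # -- dose --------------------------------------------------------------

    def beam_dose(self, beam: Beam, unit_weight: bool = False) -> DoseGrid:
        """Unnormalized dose of one beam (optionally at unit weight)."""
        depth, r, bev = self._trace(beam.geometry)
        cfg = self.cfg
        open_ray = beam.aperture.is_open(bev[..., 0], bev[..., 1])
        a = np.where(open_ray, 1.0, cfg.transmission)
        isl = (beam.geometry.sad / r) ** 2 if cfg.inverse_square else 1.0
        w = 1.0 if unit_weight else beam.weight
        vals = w * a * isl * np.exp(-cfg.mu_eff * depth)
        out = np.zeros(self.density.shape)
        out[tuple(self._idx.T)] = vals
        return DoseGrid(out, self.density.origin, self.density.spacing)

    def plan_dose(self, plan: Plan) -> tuple[DoseGrid, float]:
        """Normalized plan dose (100 at the isocenter voxel) and the rescale factor."""
        if not plan.beams:
            raise ValueError("plan has no beams")
        total = np.zeros(self.density.shape)
        for beam in plan.beams:
            total += self.beam_dose(beam).data
        iso_idx = self.density.nearest_index(np.asarray(plan.isocenter))
        if not self.body[iso_idx]:
            raise ValueError("isocenter lies outside the body")
        raw = total[iso_idx]
        if raw <= 0:
            raise ValueError("zero dose at the isocenter; cannot normalize")
        scale = 100.0 / raw
        return DoseGrid(total * scale, self.density.origin, self.density.spacing), scale


def compute_beam_dose(density: DensityGrid, beam: Beam, cfg: EngineConfig | None = None) -> DoseGrid:
    """One-shot unnormalized single-beam dose (see :class:`DoseEngine`)."""
    return DoseEngine(density, cfg).beam_dose(beam)


def compute_plan_dose(
    density: DensityGrid, plan: Plan, cfg: EngineConfig | None = None
) -> tuple[DoseGrid, float]:
    """One-shot normalized plan dose and rescale factor."""
    return DoseEngine(density, cfg).plan_dose(plan)
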