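"""Coordinate frames and the beam's-eye-view (BEV) projection.

Three right-handed Cartesian frames are chained, all in millimetres:

DCS
    DICOM patient coordinate system, LPS axes (x to the patient's left,
    y posterior, z superior), head-first supine.
ICS
    Isocenter coordinate system: the DCS translated so the beam
    isocenter is the origin.
BCS
    Beam coordinate system, fixed to the gantry/collimator with the
    isocenter as origin.  At gantry = collimator = 0 the X' axis is
    cross-plane, Y' vertical (pointing from the isocenter up toward the
    source), Z' in-plane along the patient longitudinal axis.  The
    gantry rotates about Z', the collimator about Y'; senses follow
    IEC 61217 (gantry 90 deg = beam entering from the patient's left
    for head-first supine).

The radiation source sits at (0, SAD, 0) in the BCS for every gantry
and collimator angle; the BEV plane is Y' = 0 (the isocenter plane) and
points are mapped onto it by central projection from the source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeamGeometry",
    "DegenerateProjectionError",
    "dcs_to_ics",
    "ics_to_bcs",
    "project_to_bev",
    "dcs_to_bev",
]


class DegenerateProjectionError(ValueError):
    """Raised when a point lies at or behind the source (Y' >= SAD)."""


@dataclass(frozen=True)
class BeamGeometry:
    """Isocentric beam: isocenter (DCS mm), gantry/collimator angles (deg), SAD (mm)."""

    isocenter: tuple[float, float, float]
    gantry_deg: float = 0.0
    collimator_deg: float = 0.0
    sad: float = 1000.0

    def __post_init__(self) -> None:
        if self.sad <= 0:
            raise ValueError(f"SAD must be positive, got {self.sad}")
        object.__setattr__(self, "isocenter", tuple(float(c) for c in self.isocenter))
        object.__setattr__(self, "gantry_deg", float(self.gantry_deg) % 360.0)
        object.__setattr__(self, "collimator_deg", float(self.collimator_deg) % 360.0)

    def rotation_matrix(self) -> np.ndarray:
        """3x3 proper rotation R with p_BCS = R @ p_ICS.

        Rows of R are the BCS basis vectors expressed in ICS/DCS axes:
        the Y' row always points from the isocenter toward the source.
        """
        g = np.deg2rad(self.gantry_deg)
        c = np.deg2rad(self.collimator_deg)
        # gantry-rotated, collimator-zero basis
        e_x0 = np.array([-np.cos(g), -np.sin(g), 0.0])
        e_y = np.array([np.sin(g), -np.cos(g), 0.0])
        e_z0 = np.array([0.0, 0.0, 1.0])
        # collimator spins X'/Z' about the beam axis Y'
        e_x = np.cos(c) * e_x0 + np.sin(c) * e_z0
        e_z = -np.sin(c) * e_x0 + np.cos(c) * e_z0
        return np.vstack([e_x, e_y, e_z])

    def source_position_dcs(self) -> np.ndarray:
        """DCS position of the source: isocenter + SAD along the Y' axis."""
        return np.asarray(self.isocenter) + self.sad * self.rotation_matrix()[1]

    def opposed(self) -> "BeamGeometry":
        """The parallel-opposed beam (gantry + 180 deg)."""
        return BeamGeometry(
            self.isocenter, self.gantry_deg + 180.0, self.collimator_deg, self.sad
        )


def dcs_to_ics(p: np.ndarray, geom: BeamGeometry) -> np.ndarray:
    """Translate DCS points so the isocenter is at the origin.

    ``p`` may be a single point or an (..., 3) array.
    """
    return np.asarray(p, dtype=float) - np.asarray(geom.isocenter)


def ics_to_bcs(p: np.ndarray, geom: BeamGeometry) -> np.ndarray:
    """Rotate ICS points into the gantry/collimator-fixed beam frame."""
    return np.asarray(p, dtype=float) @ geom.rotation_matrix().T


def project_to_bev(p: np.ndarray, geom: BeamGeometry) -> np.ndarray:
    """Centrally project BCS points onto the isocenter plane Y' = 0.

    The source sits at (0, SAD, 0); similar triangles give
    X_BEV = X' * SAD / (SAD - Y') and likewise for Z_BEV.  Returns an
    (..., 2) array of (X_BEV, Z_BEV).

    Raises
    ------
    DegenerateProjectionError
        If any point has Y' >= SAD (at or behind the source).
    """
    p = np.asarray(p, dtype=float)
    y = p[..., 1]
    denom = geom.sad - y
    if np.any(denom <= 0):
        raise DegenerateProjectionError(
            "point(s) at or behind the source (Y' >= SAD) cannot be projected"
        )
    mag = geom.sad / denom
    return np.stack([p[..., 0] * mag, p[..., 2] * mag], axis=-1)


def dcs_to_bev(p: np.ndarray, geom: BeamGeometry) -> np.ndarray:
    """Full chain DCS -> ICS -> BCS -> BEV for (..., 3) points."""
    return project_to_bev(ics_to_bcs(dcs_to_ics(p, geom), geom), geom)
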