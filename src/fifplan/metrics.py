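"""Dose-volume histogram and PTV dose indices.

The DVH is voxel-exact: the cumulative volume at dose d is the fraction
of structure voxels with dose >= d, with no histogram binning.  D_V is
the largest dose d such that at least the fraction V of the volume
receives >= d (lower-quantile convention on the voxel distribution);
V_D is the percentage of voxels receiving >= D.  The homogeneity index
HI = (D2% - D98%) / D50%, reported in percent, is 0 for a perfectly
uniform dose.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .grids import DoseGrid, StructureMask

__all__ = [
    "DVH",
    "DoseIndices",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "homogeneity_index",
    "dose_indices",
]


@dataclass
class DVH:
    """Sorted dose samples (% Rx, descending) of all voxels in a structure."""

    doses_desc: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.doses_desc, dtype=float).ravel()
        if d.size == 0:
            raise ValueError("empty structure: DVH undefined")
        self.doses_desc = np.sort(d)[::-1]

    @property
    def n(self) -> int:
        return self.doses_desc.size

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """(dose, fraction of volume receiving >= dose), dose ascending."""
        d = self.doses_desc[::-1]
        frac = np.arange(self.n, 0, -1) / self.n
        return d, frac


def compute_dvh(dose: DoseGrid, structure: StructureMask) -> DVH:
    if not dose.same_lattice(structure):
        raise ValueError("dose grid and structure mask are on different lattices")
    if not structure.data.any():
        raise ValueError(f"structure {structure.label!r} is empty")
    return DVH(dose.data[structure.data])


def dose_at_volume(dvh: DVH, volume_fraction: float) -> float:
    """D_V: largest dose covering at least ``volume_fraction`` of the structure."""
    if not 0 < volume_fraction < 1:
        raise ValueError(f"volume fraction must be in (0, 1), got {volume_fraction}")
    k = int(np.ceil(volume_fraction * dvh.n)) - 1
    return float(dvh.doses_desc[max(k, 0)])


def volume_at_dose(dvh: DVH, dose: float) -> float:
    """V_D: percentage of the structure volume receiving at least ``dose``."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return float(np.mean(dvh.doses_desc >= dose) * 100.0)


def homogeneity_index(dvh: DVH) -> float:
    """(D2% - D98%) / D50% in percent; 0 for uniform dose."""
    d2 = dose_at_volume(dvh, 0.02)
    d98 = dose_at_volume(dvh, 0.98)
    d50 = dose_at_volume(dvh, 0.50)
    if d50 == 0:
        raise ZeroDivisionError("D50% is zero; homogeneity index undefined")
    return float((d2 - d98) / d50 * 100.0)


@dataclass
class DoseIndices:
    """The study's PTV indices (% Rx for doses, % of structure volume for V's)."""

    d95: float
    d2: float
    d98: float
    d50: float
    d_max: float
    v95: float
    v105: float
    hi: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def dose_indices(dose: DoseGrid, structure: StructureMask) -> DoseIndices:
    dvh = compute_dvh(dose, structure)
    return DoseIndices(
        d95=dose_at_volume(dvh, 0.95),
        d2=dose_at_volume(dvh, 0.02),
        d98=dose_at_volume(dvh, 0.98),
        d50=dose_at_volume(dvh, 0.50),
        d_max=float(dvh.doses_desc[0]),
        v95=volume_at_dose(dvh, 95.0),
        v105=volume_at_dose(dvh, 105.0),
        hi=homogeneity_index(dvh),
    )
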