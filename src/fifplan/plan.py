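"""Beams and treatment plans.

A plan is a set of isocentric photon beams sharing one prescription:
two opposed lateral main beams for whole-brain irradiation, plus zero
or more low-weight sub-beams whose MLC blocks dose hotspots.  Beam
weights are relative; dose is always re-normalized to 100% of the
prescription at the isocenter voxel after computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import BeamGeometry
from .mlc import MLCAperture

__all__ = ["Beam", "Plan"]

BEAM_ROLES = ("main", "sub1", "sub2")


@dataclass
class Beam:
    id: str
    role: str
    geometry: BeamGeometry
    aperture: MLCAperture
    weight: float
    energy_mv: float = 10.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in BEAM_ROLES:
            raise ValueError(f"beam {self.id!r}: unknown role {self.role!r}")
        if self.weight < 0:
            raise ValueError(f"beam {self.id!r}: weight must be >= 0")


@dataclass
class Plan:
    beams: list[Beam]
    prescription_gy: float = 30.0
    fractions: int = 15
    normalization: str = "100% at isocenter"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.main_beams():
            raise ValueError("a plan requires at least one main beam")

    def main_beams(self) -> list[Beam]:
        return [b for b in self.beams if b.role == "main"]

    def sub_beams(self) -> list[Beam]:
        return [b for b in self.beams if b.role != "main"]

    @property
    def isocenter(self) -> tuple[float, float, float]:
        return self.main_beams()[0].geometry.isocenter
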