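"""Multileaf-collimator bank, apertures, and hotspot-blocking leaf fitting.

The blocking rule operates per leaf pair on the hotspot pixels whose
Z_BEV extent overlaps that pair's band:

* no hotspot in the band: the pair keeps its open-field positions;
* hotspot entirely on one side of the field's vertical centre line
  (X_BEV = 0): the leaf on that side advances to the hotspot edge
  nearest the centre line, covering everything outboard of it;
* hotspot crossing the centre line: the horizontal distances d1/d2
  from the centre line to the outer hotspot edges are compared and the
  leaf on the side with the larger distance sweeps across the centre
  line to cover the full hotspot extent of the row (ties go to the
  left leaf);
* two disjoint hotspot intervals on opposite sides: each side's leaf
  covers its own interval.

Leaf tips are quantized outward to 0.1 mm so coverage is never lost to
rounding.  Jaws are never moved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bev import BEVMask

__all__ = ["MLCBank", "MLCAperture", "LeafRowDecision", "fit_blocking_aperture", "blocked_region"]

LEAF_QUANTUM_MM = 0.1


@dataclass(frozen=True)
class MLCBank:
    """Leaf-pair boundaries along Z_BEV (mm), strictly increasing."""

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("leaf boundaries must be strictly increasing, length >= 2")
        object.__setattr__(self, "boundaries", b)

    @classmethod
    def truebeam_hd(cls) -> "MLCBank":
        """Default bank: 14 central 2.5-mm pairs flanked by 16 5-mm pairs per side."""
        edges = np.concatenate(
            [
                np.arange(-97.5, -17.5, 5.0),
                np.arange(-17.5, 17.5, 2.5),
                np.arange(17.5, 97.5 + 1e-9, 5.0),
            ]
        )
        return cls(tuple(edges))

    @property
    def n_pairs(self) -> int:
        return len(self.boundaries) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def pair_of(self, z: np.ndarray) -> np.ndarray:
        """Leaf-pair index for Z_BEV positions; -1 outside the bank."""
        z = np.asarray(z, dtype=float)
        edges = np.asarray(self.boundaries)
        k = np.searchsorted(edges, z, side="right") - 1
        k = np.where((z < edges[0]) | (z >= edges[-1]), -1, np.clip(k, 0, self.n_pairs - 1))
        return k


@dataclass
class MLCAperture:
    """Per-pair leaf tips (mm at the isocenter plane) plus the jaw rectangle.

    The open strip of pair ``k`` is ``left_tips[k] < X_BEV < right_tips[k]``
    intersected with the jaw rectangle ``(x1, x2, z1, z2)``.
    """

    bank: MLCBank
    left_tips: np.ndarray
    right_tips: np.ndarray
    jaws: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        self.left_tips = np.asarray(self.left_tips, dtype=float).copy()
        self.right_tips = np.asarray(self.right_tips, dtype=float).copy()
        n = self.bank.n_pairs
        if self.left_tips.shape != (n,) or self.right_tips.shape != (n,):
            raise ValueError(f"tip arrays must have shape ({n},)")
        if np.any(self.left_tips > self.right_tips + 1e-9):
            raise ValueError("left leaf tip beyond right leaf tip")
        x1, x2, z1, z2 = (float(v) for v in self.jaws)
        if x1 >= x2 or z1 >= z2:
            raise ValueError(f"degenerate jaw rectangle {self.jaws}")
        self.jaws = (x1, x2, z1, z2)

    @classmethod
    def open_field(
        cls, bank: MLCBank, jaws: tuple[float, float, float, float]
    ) -> "MLCAperture":
        """Rectangular aperture: all leaves parked at the jaw X edges."""
        n = bank.n_pairs
        x1, x2 = jaws[0], jaws[1]
        return cls(bank, np.full(n, x1), np.full(n, x2), jaws)

    def copy(self) -> "MLCAperture":
        return MLCAperture(self.bank, self.left_tips, self.right_tips, self.jaws)

    def is_open(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Boolean array: is the ray through (X_BEV, Z_BEV) unblocked."""
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        x1, x2, z1, z2 = self.jaws
        k = self.bank.pair_of(z)
        ks = np.clip(k, 0, self.bank.n_pairs - 1)
        open_leaf = (x > self.left_tips[ks]) & (x < self.right_tips[ks]) & (k >= 0)
        return open_leaf & (x > x1) & (x < x2) & (z > z1) & (z < z2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MLCAperture):
            return NotImplemented
        return (
            self.bank == other.bank
            and self.jaws == other.jaws
            and np.array_equal(self.left_tips, other.left_tips)
            and np.array_equal(self.right_tips, other.right_tips)
        )


@dataclass(frozen=True)
class LeafRowDecision:
    """Record of one pair's blocking decision (distances to outer hotspot edges)."""

    pair: int
    d_left: float
    d_right: float
    side: str  # "left" | "right" | "both" | "none"


def _runs(col: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True pixels as (start, stop) index pairs, stop inclusive."""
    idx = np.flatnonzero(col)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def _quantize_out(value: float, direction: int) -> float:
    """Round a tip outward (direction +1 rounds up, -1 down) to the leaf quantum."""
    q = LEAF_QUANTUM_MM
    if direction > 0:
        return float(np.ceil(value / q - 1e-9) * q)
    return float(np.floor(value / q + 1e-9) * q)


def fit_blocking_aperture(
    hotspots: BEVMask, bank: MLCBank, open_field: MLCAperture, center_x: float = 0.0
) -> tuple[MLCAperture, list[LeafRowDecision]]:
    """Advance leaves of a duplicated open field to cover a hotspot raster.

    Returns the fitted aperture together with the per-pair decisions.
    Covered pixels are always a superset of the hotspot pixels of each
    pair's band; pairs without hotspot keep the open-field tips.
    """
    if bank != open_field.bank:
        raise ValueError("bank mismatch between MLC bank and open-field aperture")
    aperture = open_field.copy()
    decisions: list[LeafRowDecision] = []
    px = hotspots.pixel
    zc = hotspots.z_centers()
    z_lo = zc - px / 2
    z_hi = zc + px / 2
    edges = np.asarray(bank.boundaries)
    for k in range(bank.n_pairs):
        b0, b1 = edges[k], edges[k + 1]
        rows = np.flatnonzero((z_hi > b0) & (z_lo < b1))
        if rows.size == 0:
            continue
        col = hotspots.data[:, rows].any(axis=1)
        runs = _runs(col)
        if not runs:
            continue
        # pixel-edge X extents, relative to the field centre line
        xc = hotspots.x_centers()
        ext = [(xc[a] - px / 2 - center_x, xc[b] + px / 2 - center_x) for a, b in runs]
        xmin = min(e[0] for e in ext)
        xmax = max(e[1] for e in ext)
        crossing = any(lo < 0.0 < hi for lo, hi in ext)
        if crossing:
            d_left, d_right = -xmin, xmax
            if d_right > d_left:
                side = "right"
                aperture.right_tips[k] = min(
                    aperture.right_tips[k], _quantize_out(center_x + xmin, -1)
                )
            else:
                side = "left"  # d1 = d2 ties resolve to the left leaf
                aperture.left_tips[k] = max(
                    aperture.left_tips[k], _quantize_out(center_x + xmax, +1)
                )
        else:
            left_ext = [e for e in ext if e[1] <= 0.0]
            right_ext = [e for e in ext if e[0] >= 0.0]
            d_left = -min((e[0] for e in left_ext), default=0.0)
            d_right = max((e[1] for e in right_ext), default=0.0)
            side = "both" if left_ext and right_ext else ("left" if left_ext else "right")
            if left_ext:
                inner = max(e[1] for e in left_ext)
                aperture.left_tips[k] = max(
                    aperture.left_tips[k], _quantize_out(center_x + inner, +1)
                )
            if right_ext:
                inner = min(e[0] for e in right_ext)
                aperture.right_tips[k] = min(
                    aperture.right_tips[k], _quantize_out(center_x + inner, -1)
                )
        # a leaf sweeping across the centre line may pass the parked opposite leaf
        if aperture.left_tips[k] > aperture.right_tips[k]:
            if side == "right":
                aperture.right_tips[k] = aperture.left_tips[k]
            else:
                aperture.left_tips[k] = aperture.right_tips[k]
        decisions.append(LeafRowDecision(k, float(d_left), float(d_right), side))
    return aperture, decisions


def blocked_region(
    aperture_sub: MLCAperture, aperture_main: MLCAperture, raster: BEVMask
) -> BEVMask:
    """Pixels open in the main aperture but covered by a leaf in the sub aperture."""
    if aperture_sub.bank != aperture_main.bank:
        raise ValueError("bank mismatch between sub and main apertures")
    if aperture_sub.jaws != aperture_main.jaws:
        raise ValueError("jaw mismatch between sub and main apertures")
    out = raster.empty_like()
    xx, zz = np.meshgrid(out.x_centers(), out.z_centers(), indexing="ij")
    out.data = aperture_main.is_open(xx, zz) & ~aperture_sub.is_open(xx, zz)
    return out
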