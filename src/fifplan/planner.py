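"""The semiautomatic field-in-field (FIF) planner.

Step 1 duplicates each opposed lateral main beam as a sub-beam whose
MLC blocks the beam's-eye-view projection of the 3D hotspot region
(PTV voxels above the threshold D_th, default 105% of prescription),
then splits each main beam's weight in closed form:

    f          = (D_max - D_th) / D_max
    w_main_FIF = w_main * (1 - f) = w_main * D_th / D_max
    w_sub_FIF  = w_main - w_main_FIF

so that (up to MLC transmission) doses in unblocked regions are
unchanged while blocked regions are reduced by the fraction f, pulling
the former maximum down to D_th.

Step 2 runs when Step 1 costs more than a criterion (default 1
percentage point) of the PTV's D95: the two-sub-beam plan is rebuilt
with the intermediate threshold D_ith = (D_max + D_th)/2, the residual
region above D_th in that intermediate dose is blocked by a second
sub-beam pair, and the main weights are reduced once more by
D_th / w_ithmax, where w_ithmax is the intermediate plan's PTV maximum.
Splitting the weight transfer over two shallower sub-beam pairs trades
less target coverage for the same hotspot removal.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .bev import BEVMask, find_hotspots, project_mask_to_bev
from .engine import DoseEngine, EngineConfig
from .grids import DensityGrid, DoseGrid, StructureMask
from .metrics import DoseIndices, compute_dvh, dose_at_volume, dose_indices, volume_at_dose
from .mlc import fit_blocking_aperture
from .plan import Beam, Plan

__all__ = [
    "FIFConfig",
    "StepResult",
    "PlanReport",
    "AutoFIFResult",
    "step1_weights",
    "build_step1_plan",
    "evaluate_step1",
    "build_step2_plan",
    "autofif",
]


@dataclass(frozen=True)
class FIFConfig:
    """Planner parameters: hotspot threshold, D95 criterion, raster pitch, engine."""

    d_th: float = 105.0
    criterion_pp: float = 1.0
    raster_pixel: float = 1.0
    engine: EngineConfig = field(default_factory=EngineConfig)

    def __post_init__(self) -> None:
        if self.d_th <= 0:
            raise ValueError("D_th must be positive")
        if self.raster_pixel <= 0:
            raise ValueError("raster pixel must be positive")


def step1_weights(d_max: float, d_th: float, w_main: float = 1.0) -> tuple[float, float, float]:
    """Closed-form Step-1 weight split (f, w_main_FIF, w_sub_FIF).

    ``d_max`` is the original plan's maximum dose and ``d_th`` the
    hotspot threshold, both in % of prescription.  When d_max <= d_th
    there is no hotspot and the split is the no-op (0, w_main, 0).
    """
    if d_th <= 0:
        raise ValueError("D_th must be positive")
    if w_main < 0:
        raise ValueError("main-beam weight must be >= 0")
    if d_max <= d_th:
        return 0.0, w_main, 0.0
    f = (d_max - d_th) / d_max
    w_main_fif = w_main * (1.0 - f)
    return f, w_main_fif, w_main - w_main_fif


@dataclass
class StepResult:
    """Outcome of one sub-beam-adding stage."""

    plan: Plan
    dose: DoseGrid
    scale: float
    applied: bool
    d_max: float
    threshold: float
    f: float = 0.0
    notice: str = ""


def _blocked_sub_beams(
    hot: StructureMask, plan: Plan, raster_pixel: float, role: str, weights: dict[str, float]
) -> list[Beam]:
    """One blocking sub-beam per main beam, MLC fitted to the hotspot projection."""
    subs = []
    for i, main in enumerate(plan.main_beams(), start=1):
        raster = BEVMask.for_field(main.aperture.jaws, pixel=raster_pixel)
        bev_hot = project_mask_to_bev(hot, main.geometry, raster)
        aperture, _ = fit_blocking_aperture(bev_hot, main.aperture.bank, main.aperture)
        subs.append(
            Beam(
                id=f"{role}_{i}",
                role=role,
                geometry=main.geometry,
                aperture=aperture,
                weight=weights[main.id],
                energy_mv=main.energy_mv,
            )
        )
    return subs


def _build_blocking_stage(
    plan: Plan,
    dose_ref: DoseGrid,
    ptv: StructureMask,
    threshold: float,
    raster_pixel: float,
    engine: DoseEngine,
    role: str,
) -> StepResult:
    """Shared Step-1 machinery: block `dose_ref > threshold` within the PTV,
    reduce the current main weights by threshold/d_max, recompute dose."""
    dvh = compute_dvh(dose_ref, ptv)
    d_max = float(dvh.doses_desc[0])
    if d_max <= threshold:
        return StepResult(
            plan, dose_ref, 1.0, False, d_max, threshold,
            notice=f"no voxel above {threshold}%: FIF unnecessary",
        )
    hot = find_hotspots(dose_ref, threshold, within=ptv)
    f = (d_max - threshold) / d_max
    sub_weights: dict[str, float] = {}
    mains = []
    for main in plan.main_beams():
        _, w_main_fif, w_sub = step1_weights(d_max, threshold, main.weight)
        sub_weights[main.id] = w_sub
        reduced = copy.copy(main)
        reduced.weight = w_main_fif
        mains.append(reduced)
    subs = _blocked_sub_beams(hot, plan, raster_pixel, role, sub_weights)
    new_plan = Plan(
        mains + [b for b in plan.sub_beams()] + subs,
        prescription_gy=plan.prescription_gy,
        fractions=plan.fractions,
        normalization=plan.normalization,
    )
    dose, scale = engine.plan_dose(new_plan)
    return StepResult(new_plan, dose, scale, True, d_max, threshold, f=f)


def build_step1_plan(
    original: Plan,
    dose_orig: DoseGrid,
    density: DensityGrid,
    ptv: StructureMask,
    cfg: FIFConfig | None = None,
    engine: DoseEngine | None = None,
) -> StepResult:
    """Two-sub-beam FIF plan blocking the original plan's hotspots above D_th."""
    cfg = cfg or FIFConfig()
    engine = engine or DoseEngine(density, cfg.engine)
    return _build_blocking_stage(
        original, dose_orig, ptv, cfg.d_th, cfg.raster_pixel, engine, role="sub1"
    )


def evaluate_step1(dose_orig: DoseGrid, dose_fif: DoseGrid, ptv: StructureMask) -> float:
    """Reduction of the PTV's D95 in percentage points (original minus FIF)."""
    d95_orig = dose_at_volume(compute_dvh(dose_orig, ptv), 0.95)
    d95_fif = dose_at_volume(compute_dvh(dose_fif, ptv), 0.95)
    return float(d95_orig - d95_fif)


def build_step2_plan(
    original: Plan,
    dose_orig: DoseGrid,
    density: DensityGrid,
    ptv: StructureMask,
    cfg: FIFConfig | None = None,
    engine: DoseEngine | None = None,
) -> StepResult:
    """Four-sub-beam FIF plan (FIF-4SF).

    The first sub-beam pair blocks the original plan's region above the
    intermediate threshold D_ith = (D_max + D_th)/2 with the Step-1
    weight split evaluated at D_ith; the second pair blocks whatever
    still exceeds D_th in that intermediate plan, with the main weights
    reduced by D_th / w_ithmax.
    """
    cfg = cfg or FIFConfig()
    engine = engine or DoseEngine(density, cfg.engine)
    dvh = compute_dvh(dose_orig, ptv)
    d_max = float(dvh.doses_desc[0])
    if d_max <= cfg.d_th:
        return StepResult(
            original, dose_orig, 1.0, False, d_max, cfg.d_th,
            notice=f"no voxel above {cfg.d_th}%: FIF unnecessary",
        )
    d_ith = (d_max + cfg.d_th) / 2.0
    stage1 = _build_blocking_stage(
        original, dose_orig, ptv, d_ith, cfg.raster_pixel, engine, role="sub1"
    )
    w_ithmax = float(compute_dvh(stage1.dose, ptv).doses_desc.max())
    if w_ithmax <= cfg.d_th:
        stage1.notice = (
            f"intermediate maximum {w_ithmax:.2f}% <= D_th {cfg.d_th}%: second sub-beam pair skipped"
        )
        return stage1
    low_hot = find_hotspots(stage1.dose, cfg.d_th, within=ptv)
    sub2_weights: dict[str, float] = {}
    mains = []
    for main in stage1.plan.main_beams():
        w_main_2nd = main.weight * cfg.d_th / w_ithmax
        sub2_weights[main.id] = main.weight - w_main_2nd
        reduced = copy.copy(main)
        reduced.weight = w_main_2nd
        mains.append(reduced)
    subs2 = _blocked_sub_beams(low_hot, stage1.plan, cfg.raster_pixel, "sub2", sub2_weights)
    plan4 = Plan(
        mains + stage1.plan.sub_beams() + subs2,
        prescription_gy=original.prescription_gy,
        fractions=original.fractions,
        normalization=original.normalization,
    )
    dose4, scale4 = engine.plan_dose(plan4)
    out = StepResult(plan4, dose4, scale4, True, d_max, cfg.d_th, f=stage1.f)
    out.notice = f"D_ith={d_ith:.2f}%, w_ithmax={w_ithmax:.2f}%"
    return out


@dataclass
class PlanReport:
    """Dose indices and weight table for the original and selected plans."""

    scheme: str  # "none" | "FIF" | "FIF-4SF"
    d_th: float
    criterion_pp: float
    d_max_original: float
    f: float
    delta_d95_step1: float
    delta_d95_final: float
    indices_original: DoseIndices
    indices_final: DoseIndices
    v_at_dth_original: float
    v_at_dth_final: float
    weights: list[dict]
    notice: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["indices_original"] = self.indices_original.to_dict()
        d["indices_final"] = self.indices_final.to_dict()
        return d

    def summary(self) -> str:
        lines = [
            f"scheme: {self.scheme}",
            f"D_th = {self.d_th}%  criterion = {self.criterion_pp} pp  "
            f"D_max(original, PTV) = {self.d_max_original:.2f}%  f = {self.f:.4f}",
            f"delta D95: step1 = {self.delta_d95_step1:.2f} pp, final = {self.delta_d95_final:.2f} pp",
            f"V_{self.d_th:g}%(PTV): {self.v_at_dth_original:.2f}% -> {self.v_at_dth_final:.2f}%",
            "beam weights:",
        ]
        for w in self.weights:
            lines.append(f"  {w['id']:<8s} {w['role']:<5s} {w['weight']:.4f}")
        if self.notice:
            lines.append(f"note: {self.notice}")
        return "\n".join(lines)


@dataclass
class AutoFIFResult:
    plan: Plan
    dose: DoseGrid
    report: PlanReport
    dose_original: DoseGrid
    step1: StepResult
    step2: StepResult | None = None


def autofif(
    original: Plan,
    density: DensityGrid,
    ptv: StructureMask,
    cfg: FIFConfig | None = None,
    engine: DoseEngine | None = None,
    dose_orig: DoseGrid | None = None,
) -> AutoFIFResult:
    """Run the full two-step scheme and report dose indices.

    Step 1 is always attempted; if it reduces the PTV's D95 by more
    than the criterion, its plan is discarded and the four-sub-beam
    Step 2 plan is built instead.
    """
    cfg = cfg or FIFConfig()
    engine = engine or DoseEngine(density, cfg.engine)
    if dose_orig is None:
        dose_orig, _ = engine.plan_dose(original)
    step1 = build_step1_plan(original, dose_orig, density, ptv, cfg, engine)
    step2 = None
    if not step1.applied:
        scheme, selected = "none", step1
        delta1 = delta_final = 0.0
    else:
        delta1 = evaluate_step1(dose_orig, step1.dose, ptv)
        if delta1 > cfg.criterion_pp:
            step2 = build_step2_plan(original, dose_orig, density, ptv, cfg, engine)
            scheme, selected = "FIF-4SF", step2
            delta_final = evaluate_step1(dose_orig, step2.dose, ptv)
        else:
            scheme, selected = "FIF", step1
            delta_final = delta1

    dvh_orig = compute_dvh(dose_orig, ptv)
    dvh_final = compute_dvh(selected.dose, ptv)
    report = PlanReport(
        scheme=scheme,
        d_th=cfg.d_th,
        criterion_pp=cfg.criterion_pp,
        d_max_original=step1.d_max,
        f=selected.f,
        delta_d95_step1=delta1,
        delta_d95_final=delta_final,
        indices_original=dose_indices(dose_orig, ptv),
        indices_final=dose_indices(selected.dose, ptv),
        v_at_dth_original=volume_at_dose(dvh_orig, cfg.d_th),
        v_at_dth_final=volume_at_dose(dvh_final, cfg.d_th),
        weights=[
            {"id": b.id, "role": b.role, "weight": float(b.weight)} for b in selected.plan.beams
        ],
        notice=selected.notice,
    )
    return AutoFIFResult(selected.plan, selected.dose, report, dose_orig, step1, step2)
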