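"""File formats: JSON plans, NRRD grids, DVH CSV, optional DICOM RT Dose.

The interchange formats are deliberately plain: the plan is a JSON
document (human-diffable, schema-checked on read, unknown fields
preserved) and grids are NRRD volumes whose header carries origin and
spacing in DCS millimetres.  DICOM RT Dose import/export is a thin
optional adapter; full clinical DICOM fidelity is out of scope.

Grid orientation: arrays are indexed (x, y, z) along the DICOM LPS
axes with 0-based indices and the origin at the centre of voxel
(0, 0, 0).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import SimpleITK as sitk

from .geometry import BeamGeometry
from .grids import DensityGrid, DoseGrid, Grid3D, StructureMask
from .metrics import DVH
from .mlc import MLCAperture, MLCBank
from .plan import Beam, Plan

__all__ = [
    "PlanSchemaError",
    "read_plan",
    "write_plan",
    "read_dose",
    "write_dose",
    "read_density",
    "write_density",
    "read_mask",
    "write_mask",
    "write_dvh_csv",
    "write_rtdose",
    "read_rtdose",
]


class PlanSchemaError(ValueError):
    """A plan document violates the schema; the message names the field path."""


# ---------------------------------------------------------------------------
# plan JSON

_BEAM_KEYS = {
    "id", "role", "gantry_deg", "collimator_deg", "isocenter_mm", "sad_mm",
    "jaws_mm", "mlc", "weight", "energy_mv",
}
_PLAN_KEYS = {"prescription", "normalization", "beams"}


def _beam_to_dict(beam: Beam) -> dict:
    d = {
        "id": beam.id,
        "role": beam.role,
        "gantry_deg": beam.geometry.gantry_deg,
        "collimator_deg": beam.geometry.collimator_deg,
        "isocenter_mm": list(beam.geometry.isocenter),
        "sad_mm": beam.geometry.sad,
        "jaws_mm": {
            "x1": beam.aperture.jaws[0],
            "x2": beam.aperture.jaws[1],
            "z1": beam.aperture.jaws[2],
            "z2": beam.aperture.jaws[3],
        },
        "mlc": {
            "boundaries_mm": list(beam.aperture.bank.boundaries),
            "left_tips_mm": beam.aperture.left_tips.tolist(),
            "right_tips_mm": beam.aperture.right_tips.tolist(),
        },
        "weight": beam.weight,
        "energy_mv": beam.energy_mv,
    }
    d.update(beam.extra)
    return d


def plan_to_dict(plan: Plan) -> dict:
    doc = {
        "prescription": {"total_gy": plan.prescription_gy, "fractions": plan.fractions},
        "normalization": plan.normalization,
        "beams": [_beam_to_dict(b) for b in plan.beams],
    }
    doc.update(plan.extra)
    return doc


def write_plan(plan: Plan, path: str | Path) -> None:
    Path(path).write_text(json.dumps(plan_to_dict(plan), indent=2) + "\n")


def _require(doc: dict, key: str, path: str) -> Any:
    if key not in doc:
        raise PlanSchemaError(f"missing field {path}.{key}")
    return doc[key]


def _beam_from_dict(d: dict, i: int) -> Beam:
    where = f"beams[{i}]"
    if not isinstance(d, dict):
        raise PlanSchemaError(f"{where} must be an object")
    bid = _require(d, "id", where)
    where = f"beams[{i}] (id={bid!r})"
    geom = BeamGeometry(
        tuple(_require(d, "isocenter_mm", where)),
        _require(d, "gantry_deg", where),
        _require(d, "collimator_deg", where),
        _require(d, "sad_mm", where),
    )
    jaws_d = _require(d, "jaws_mm", where)
    for k in ("x1", "x2", "z1", "z2"):
        _require(jaws_d, k, f"{where}.jaws_mm")
    jaws = (jaws_d["x1"], jaws_d["x2"], jaws_d["z1"], jaws_d["z2"])
    mlc_d = _require(d, "mlc", where)
    bank = MLCBank(tuple(_require(mlc_d, "boundaries_mm", f"{where}.mlc")))
    aperture = MLCAperture(
        bank,
        np.asarray(_require(mlc_d, "left_tips_mm", f"{where}.mlc")),
        np.asarray(_require(mlc_d, "right_tips_mm", f"{where}.mlc")),
        jaws,
    )
    try:
        beam = Beam(
            id=str(bid),
            role=str(_require(d, "role", where)),
            geometry=geom,
            aperture=aperture,
            weight=float(_require(d, "weight", where)),
            energy_mv=float(d.get("energy_mv", 10.0)),
            extra={k: v for k, v in d.items() if k not in _BEAM_KEYS},
        )
    except ValueError as exc:
        raise PlanSchemaError(f"{where}: {exc}") from exc
    return beam


def plan_from_dict(doc: dict) -> Plan:
    rx = _require(doc, "prescription", "$")
    beams_doc = _require(doc, "beams", "$")
    if not isinstance(beams_doc, list) or not beams_doc:
        raise PlanSchemaError("$.beams must be a non-empty list")
    beams = [_beam_from_dict(b, i) for i, b in enumerate(beams_doc)]
    try:
        return Plan(
            beams,
            prescription_gy=float(_require(rx, "total_gy", "$.prescription")),
            fractions=int(_require(rx, "fractions", "$.prescription")),
            normalization=str(doc.get("normalization", "100% at isocenter")),
            extra={k: v for k, v in doc.items() if k not in _PLAN_KEYS},
        )
    except PlanSchemaError:
        raise
    except ValueError as exc:
        raise PlanSchemaError(str(exc)) from exc


def read_plan(path: str | Path) -> Plan:
    return plan_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# NRRD grids (SimpleITK carries origin/spacing in the header)


def _grid_to_image(grid: Grid3D, dtype) -> sitk.Image:
    # sitk expects (z, y, x) arrays; our grids are (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.data.astype(dtype).T))
    img.SetOrigin(tuple(grid.origin))
    img.SetSpacing(tuple(grid.spacing))
    return img


def _image_to_arrays(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D grid, got {img.GetDimension()}D")
    data = sitk.GetArrayFromImage(img).T
    return data, np.asarray(img.GetOrigin()), np.asarray(img.GetSpacing())


def write_dose(dose: DoseGrid, path: str | Path, prescription_gy: float | None = None) -> None:
    """Dose in % of prescription; the prescription (Gy) rides in the header."""
    img = _grid_to_image(dose, np.float64)
    img.SetMetaData("dose_units", "percent_of_prescription")
    if prescription_gy is not None:
        img.SetMetaData("prescription_gy", repr(float(prescription_gy)))
    sitk.WriteImage(img, str(path))


def read_dose(path: str | Path) -> DoseGrid:
    data, origin, spacing = _image_to_arrays(path)
    return DoseGrid(data, origin, spacing)


def write_density(density: DensityGrid, path: str | Path) -> None:
    sitk.WriteImage(_grid_to_image(density, np.float64), str(path))


def read_density(path: str | Path) -> DensityGrid:
    data, origin, spacing = _image_to_arrays(path)
    return DensityGrid(data, origin, spacing)


def write_mask(mask: StructureMask, path: str | Path) -> None:
    img = _grid_to_image(mask, np.uint8)
    img.SetMetaData("label", mask.label)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path, label: str = "") -> StructureMask:
    data, origin, spacing = _image_to_arrays(path)
    img = sitk.ReadImage(str(path))
    if not label and img.HasMetaDataKey("label"):
        label = img.GetMetaData("label")
    return StructureMask(data > 0, origin, spacing, label=label)


def write_dvh_csv(dvh: DVH, path: str | Path) -> None:
    """Two-column CSV: dose (% Rx), fraction of volume receiving >= dose."""
    dose, frac = dvh.cumulative()
    with open(path, "w") as fh:
        fh.write("dose_percent,volume_fraction\n")
        for d, v in zip(dose, frac):
            fh.write(f"{d:.6g},{v:.6g}\n")


# ---------------------------------------------------------------------------
# optional DICOM RT Dose adapter


def write_rtdose(dose: DoseGrid, path: str | Path, prescription_gy: float = 30.0) -> None:
    """Export as a minimal DICOM RT Dose (absolute Gy, 32-bit scaled ints)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import generate_uid, ExplicitVRLittleEndian

    gy = dose.data * prescription_gy / 100.0
    scaling = max(gy.max(), 1e-9) / (2**31 - 1)
    pixels = np.rint(gy / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.PatientOrientation = []
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    # frames along z, rows along y, columns along x
    ds.Rows = dose.shape[1]
    ds.Columns = dose.shape[0]
    ds.NumberOfFrames = dose.shape[2]
    ds.PixelSpacing = [float(dose.spacing[1]), float(dose.spacing[0])]
    ds.SliceThickness = float(dose.spacing[2])
    ds.ImagePositionPatient = [float(v) for v in dose.origin]
    ds.GridFrameOffsetVector = [float(k * dose.spacing[2]) for k in range(dose.shape[2])]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseGridScaling = float(scaling)
    ds.PixelData = np.ascontiguousarray(pixels.T).tobytes()  # (z, y, x) order
    ds.save_as(str(path), enforce_file_format=True)


def read_rtdose(path: str | Path, prescription_gy: float = 30.0) -> DoseGrid:
    """Import an RT Dose file back into % of prescription."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ValueError(f"{path}: not an RT Dose file")
    arr = ds.pixel_array.astype(np.float64) * float(ds.DoseGridScaling)  # (z, y, x)
    data = arr.T * 100.0 / prescription_gy
    origin = np.asarray([float(v) for v in ds.ImagePositionPatient])
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    spacing = np.asarray([float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz])
    return DoseGrid(data, origin, spacing)
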