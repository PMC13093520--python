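"""Radiotherapy file I/O.

Two ingestion paths are provided: standard DICOM (RTSTRUCT contour sets and
RTDOSE grids, read with pydicom) and a lightweight internal *case bundle* —
a directory with a human-readable JSON manifest plus compressed dense arrays
— so that tests and synthetic cohorts need no DICOM fixtures.

Only axis-aligned, non-oblique DICOM geometry is supported; oblique
direction cosines are rejected with :class:`~dirqa.errors.GeometryError`
rather than silently resampled.
"""
from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import CaseBundle, ContourSet, DoseGrid, ROLES, StructureMask, VoxelGrid
from .errors import FormatError, GeometryError, IntegrityError

__all__ = [
    "DEFAULT_ROLE_PATTERNS",
    "assign_role",
    "read_rtstruct",
    "read_rtdose",
    "write_rtstruct",
    "write_rtdose",
    "read_case_bundle",
    "write_case_bundle",
    "VoxelGrid",
    "ContourSet",
    "DoseGrid",
    "CaseBundle",
]

#: Default ROI-name -> role map, applied case-insensitively in order; the
#: first matching pattern wins and unmatched names fall back to "other".
#: Clinics encode roles in free-text ROI names, so this table is user-editable:
#: pass your own ``(role, regex)`` sequence to :func:`assign_role` /
#: :func:`read_rtstruct`.
DEFAULT_ROLE_PATTERNS: Tuple[Tuple[str, str], ...] = (
    ("PTV", r"^\s*ptv"),
    ("CTV-T", r"^\s*ctv[\s_\-]*t"),
    ("CTV-N", r"^\s*ctv[\s_\-]*n"),
    ("GTVp", r"^\s*gtv[\s_\-]*p"),
    ("GTVn", r"^\s*gtv[\s_\-]*n"),
)


def assign_role(
    label: str, patterns: Optional[Sequence[Tuple[str, str]]] = None
) -> str:
    """Map an ROI label to a structure role via the first matching pattern."""
    if patterns is None:
        patterns = DEFAULT_ROLE_PATTERNS
    for role, pat in patterns:
        if role not in ROLES:
            raise FormatError(f"pattern table maps to unknown role {role!r}")
        if re.search(pat, label, flags=re.IGNORECASE):
            return role
    return "other"


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

_PLANARITY_TOL_MM = 1e-3


def read_rtstruct(
    path, role_patterns: Optional[Sequence[Tuple[str, str]]] = None
) -> List[ContourSet]:
    """Read a DICOM RTSTRUCT file into one :class:`ContourSet` per ROI.

    ROI labels are preserved verbatim; roles are assigned from
    ``role_patterns`` (default :data:`DEFAULT_ROLE_PATTERNS`).
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if not hasattr(ds, "StructureSetROISequence"):
        raise FormatError(f"{path}: no StructureSetROISequence; not an RTSTRUCT?")
    names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    out: List[ContourSet] = []
    for roi in getattr(ds, "ROIContourSequence", []):
        number = int(roi.ReferencedROINumber)
        label = names.get(number, f"ROI-{number}")
        if not hasattr(roi, "ContourSequence"):
            raise FormatError(f"ROI {label!r}: missing contour-data sequence")
        polygons: List[Tuple[float, np.ndarray]] = []
        for contour in roi.ContourSequence:
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            if data.shape[0] < 3:
                raise FormatError(f"ROI {label!r}: contour with < 3 vertices")
            zs = data[:, 2]
            if np.ptp(zs) > _PLANARITY_TOL_MM:
                raise FormatError(
                    f"ROI {label!r}: non-planar contour (z spread {np.ptp(zs):.3g} mm)"
                )
            polygons.append((float(zs.mean()), data[:, :2]))
        out.append(
            ContourSet(label=label, role=assign_role(label, role_patterns),
                       polygons=polygons)
        )
    return out


def _check_axis_aligned(cosines: Sequence[float], what: str) -> None:
    expected = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)
    if not np.allclose(np.asarray(cosines, dtype=float), expected, atol=1e-4):
        raise GeometryError(
            f"{what}: oblique orientation {list(cosines)} is unsupported; "
            "only axis-aligned (identity direction cosines) grids are handled"
        )


def read_rtdose(path) -> DoseGrid:
    """Read a DICOM RTDOSE (GRID type) into a :class:`DoseGrid` in Gy."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    if not hasattr(ds, "DoseGridScaling"):
        raise FormatError(f"{path}: no DoseGridScaling; not an RTDOSE?")
    _check_axis_aligned(ds.ImageOrientationPatient, str(path))
    scaling = float(ds.DoseGridScaling)
    if scaling == 0.0:
        warnings.warn(f"{path}: DoseGridScaling is 0; dose will be all zero")
    raw = ds.pixel_array  # (frames, rows, cols) = (z, y, x)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) > 1:
        dz = np.diff(offsets)
        if not np.allclose(dz, dz[0], atol=1e-4):
            raise GeometryError(f"{path}: non-uniform frame offsets are unsupported")
        dz = float(dz[0])
    else:
        dz = 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)  # row spacing, column spacing
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = VoxelGrid(
        origin=origin,
        spacing=(dx, dy, dz),
        shape=(raw.shape[2], raw.shape[1], raw.shape[0]),
    )
    values = np.ascontiguousarray(raw.astype(float).transpose(2, 1, 0)) * scaling
    return DoseGrid(grid=grid, values=values)


def _base_dataset(sop_class_uid: str, modality: str):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "dirqa^synthetic"
    ds.PatientID = "DIRQA"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    return ds


def write_rtstruct(contour_sets: Sequence[ContourSet], path) -> None:
    """Write a minimal valid RTSTRUCT (enough for interoperability tests)."""
    from pydicom.dataset import Dataset
    from pydicom.uid import generate_uid

    ds = _base_dataset("1.2.840.10008.5.1.4.1.1.481.3", "RTSTRUCT")
    ds.StructureSetLabel = "dirqa"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    for i, cs in enumerate(contour_sets, start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ROIName = cs.label
        roi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ContourSequence = []
        for z, verts in cs.polygons:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = verts.shape[0]
            data = np.column_stack([verts, np.full(verts.shape[0], z)])
            c.ContourData = [float(v) for v in data.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
        obs = Dataset()
        obs.ObservationNumber = i
        obs.ReferencedROINumber = i
        obs.RTROIInterpretedType = "ORGAN"
        ds.RTROIObservationsSequence.append(obs)
    ds.save_as(str(path), enforce_file_format=True)


def write_rtdose(dose: DoseGrid, path, scaling: float = 1e-4) -> None:
    """Write a minimal valid RTDOSE (GRID, 32-bit, ``scaling`` Gy per unit)."""
    ds = _base_dataset("1.2.840.10008.5.1.4.1.1.481.2", "RTDOSE")
    g = dose.grid
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = list(g.origin)
    ds.PixelSpacing = [g.spacing[1], g.spacing[0]]  # row, column
    ds.GridFrameOffsetVector = [g.spacing[2] * k for k in range(g.shape[2])]
    ds.DoseGridScaling = scaling
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = g.shape[2]
    ds.Rows = g.shape[1]
    ds.Columns = g.shape[0]
    stored = np.round(dose.values / scaling).astype(np.uint32)
    ds.PixelData = np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Internal case bundle
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.json"
_MASKS = "masks.npz"
_DOSES = "doses.npz"


def write_case_bundle(bundle: CaseBundle, path) -> None:
    """Write a bundle directory: JSON manifest + compressed dense arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "dirqa-case-bundle/1",
        "case_id": bundle.case_id,
        "grid": {
            "origin": list(bundle.grid.origin),
            "spacing": list(bundle.grid.spacing),
            "shape": list(bundle.grid.shape),
        },
        "structures": {},
        "doses": {},
        "prescriptions": dict(bundle.prescriptions),
        "contours": {},
        "meta": bundle.meta,
    }
    masks: Dict[str, np.ndarray] = {}
    for prov, structs in bundle.structures.items():
        manifest["structures"][prov] = {}
        for label, m in structs.items():
            key = f"{prov}/{label}"
            masks[key] = m.occupancy
            manifest["structures"][prov][label] = {
                "role": m.role,
                "array": key,
                "grid": {
                    "origin": list(m.grid.origin),
                    "spacing": list(m.grid.spacing),
                    "shape": list(m.grid.shape),
                },
            }
    doses: Dict[str, np.ndarray] = {}
    for plan, d in bundle.doses.items():
        doses[plan] = d.values
        manifest["doses"][plan] = {
            "array": plan,
            "grid": {
                "origin": list(d.grid.origin),
                "spacing": list(d.grid.spacing),
                "shape": list(d.grid.shape),
            },
        }
    for prov, csets in bundle.contours.items():
        manifest["contours"][prov] = [
            {
                "label": cs.label,
                "role": cs.role,
                "polygons": [
                    {"z": z, "xy": verts.tolist()} for z, verts in cs.polygons
                ],
            }
            for cs in csets
        ]
    np.savez_compressed(path / _MASKS, **masks)
    np.savez_compressed(path / _DOSES, **doses)
    (path / _MANIFEST).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _grid_from_json(d) -> VoxelGrid:
    return VoxelGrid(origin=tuple(d["origin"]), spacing=tuple(d["spacing"]),
                     shape=tuple(d["shape"]))


def read_case_bundle(path) -> CaseBundle:
    """Read a bundle directory, verifying manifest/payload integrity."""
    path = Path(path)
    mpath = path / _MANIFEST
    if not mpath.exists():
        raise IntegrityError(f"{path}: no {_MANIFEST}")
    manifest = json.loads(mpath.read_text())
    if manifest.get("format") != "dirqa-case-bundle/1":
        raise FormatError(f"{path}: unknown bundle format {manifest.get('format')!r}")
    with np.load(path / _MASKS) as z:
        mask_arrays = {k: z[k] for k in z.files}
    with np.load(path / _DOSES) as z:
        dose_arrays = {k: z[k] for k in z.files}

    missing: List[str] = []
    structures: Dict[str, Dict[str, StructureMask]] = {}
    for prov, structs in manifest["structures"].items():
        structures[prov] = {}
        for label, rec in structs.items():
            if rec["array"] not in mask_arrays:
                missing.append(f"mask:{rec['array']}")
                continue
            structures[prov][label] = StructureMask(
                label=label,
                role=rec["role"],
                grid=_grid_from_json(rec["grid"]),
                occupancy=mask_arrays[rec["array"]],
            )
    doses: Dict[str, DoseGrid] = {}
    for plan, rec in manifest["doses"].items():
        if rec["array"] not in dose_arrays:
            missing.append(f"dose:{rec['array']}")
            continue
        doses[plan] = DoseGrid(grid=_grid_from_json(rec["grid"]),
                               values=dose_arrays[rec["array"]])
    if missing:
        raise IntegrityError(f"{path}: manifest keys without payload: {missing}")
    contours: Dict[str, List[ContourSet]] = {}
    for prov, csets in manifest.get("contours", {}).items():
        contours[prov] = [
            ContourSet(
                label=rec["label"],
                role=rec["role"],
                polygons=[
                    (p["z"], np.asarray(p["xy"], dtype=float))
                    for p in rec["polygons"]
                ],
            )
            for rec in csets
        ]
    return CaseBundle(
        case_id=manifest["case_id"],
        grid=_grid_from_json(manifest["grid"]),
        structures=structures,
        doses=doses,
        prescriptions={k: float(v) for k, v in manifest["prescriptions"].items()},
        contours=contours,
        meta=manifest.get("meta", {}),
    )
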