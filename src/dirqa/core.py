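"""Shared domain types for radiotherapy target-volume QA.

All geometry lives on axis-aligned voxel grids in patient millimetre
coordinates, axis order (x, y, z).  Anisotropic spacing is supported
throughout (head-and-neck planning CTs typically use 2.5 mm slices with
~1 mm in-plane resolution).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import GeometryError, ValidationError

#: Recognized structure roles.  GTVp / GTVn are primary / nodal gross tumor
#: volumes; CTV-T / CTV-N the corresponding clinical target volumes; PTV the
#: planning target volume obtained by margin expansion of a CTV.
ROLES = ("GTVp", "GTVn", "CTV-T", "CTV-N", "PTV", "other")

#: Roles belonging to the "tumor" analysis subset (primary disease chain).
TUMOR_ROLES = ("GTVp", "CTV-T")
#: Roles belonging to the "node" analysis subset (nodal disease chain).
NODE_ROLES = ("GTVn", "CTV-N")


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: voxel center (i,j,k) = origin + spacing*(i,j,k)."""

    origin: Tuple[float, float, float]
    spacing: Tuple[float, float, float]
    shape: Tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValidationError("grid origin/spacing/shape must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacings must be positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValidationError(f"shape entries must be >= 1, got {self.shape}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Voxel index (possibly fractional) -> patient mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + np.asarray(self.spacing) * idx

    def mm_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Patient mm coordinates -> fractional voxel index."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis, in mm."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """(n, 3) mm coordinates of all voxel centers, or of ``mask`` foreground."""
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.index_to_mm(idx)

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class ContourSet:
    """Planar polygons of one structure: (slice z mm, (n,2) xy vertices mm).

    Inner/outer status of overlapping polygons on one slice is not encoded;
    it is resolved by the even-odd rule at rasterization time.
    """

    label: str
    role: str = "other"
    polygons: List[Tuple[float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ROLES}")
        checked = []
        for z, verts in self.polygons:
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ValidationError(
                    f"polygon of {self.label!r} must be (n>=3, 2) xy vertices"
                )
            checked.append((float(z), verts))
        self.polygons = checked


@dataclass
class StructureMask:
    """Binary voxel occupancy of one target on an axis-aligned grid."""

    label: str
    role: str
    grid: VoxelGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.grid.shape:
            raise GeometryError(
                f"occupancy shape {self.occupancy.shape} != grid shape {self.grid.shape}"
            )
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_cc(self) -> float:
        """Foreground volume in cm^3 (voxel count x voxel volume)."""
        return self.voxel_count * self.grid.voxel_volume_mm3 / 1000.0

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def centroid_mm(self) -> np.ndarray:
        if self.is_empty:
            raise GeometryError(f"centroid of empty mask {self.label!r}")
        return self.grid.index_to_mm(np.argwhere(self.occupancy).mean(axis=0))


@dataclass
class DoseGrid:
    """Scalar absorbed dose in Gy on its own voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"dose shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("dose values must be finite and >= 0")


@dataclass
class CaseBundle:
    """One paired planning/replanning case.

    ``structures`` maps provenance ("RO" for physician-delineated, "DIR" for
    registration-propagated) to label-keyed masks; ``doses`` maps plan ids
    ("RO", "DIR", or replicate ids like "RO_rep0") to dose grids;
    ``prescriptions`` maps structure labels to prescribed dose in Gy.
    """

    case_id: str
    grid: VoxelGrid
    structures: Dict[str, Dict[str, StructureMask]]
    doses: Dict[str, DoseGrid] = field(default_factory=dict)
    prescriptions: Dict[str, float] = field(default_factory=dict)
    contours: Dict[str, List[ContourSet]] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prov, structs in self.structures.items():
            for label, mask in structs.items():
                if mask.label != label:
                    raise ValidationError(
                        f"bundle {self.case_id}: key {label!r} != mask label {mask.label!r}"
                    )
        for label in self.prescriptions:
            known = {l for s in self.structures.values() for l in s}
            if label not in known:
                raise ValidationError(
                    f"bundle {self.case_id}: prescription for unknown structure {label!r}"
                )

    def labels(self, provenance: str) -> List[str]:
        return sorted(self.structures.get(provenance, {}))
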