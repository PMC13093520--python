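"""Geometric agreement metrics between paired target volumes.

Implements the standard segmentation-QA trio on binary masks sharing one
grid:

* **DSC** — volumetric Dice overlap ``2|A∩B| / (|A|+|B|)``, with the
  kappa-style qualitative agreement scale (0 none … 0.81–1.00 almost
  perfect).
* **HD / HD95** — Hausdorff distance between the two boundary surfaces and
  its outlier-robust 95th-percentile variant.  The percentile is taken per
  direction and the maximum of the two directions is reported (the most
  common symmetric convention in segmentation QA); percentiles use linear
  interpolation between order statistics.
* **sDSC_τ** — symmetric surface Dice at tolerance τ: the fraction of the
  two surfaces lying within τ of each other,
  ``(|{a : d(a,B) ≤ τ}| + |{b : d(b,A) ≤ τ}|) / (|A| + |B|)`` over surface
  *element counts*.  τ = 0 uses a 1e-6 mm numerical tolerance and measures
  exactly-matching surface points; because surface elements are boundary
  face centers, sDSC_0mm is meaningful (and grid-dependent) when two masks
  are compared on the same grid.

Surface elements are the centers of exposed voxel faces (foreground voxel
adjacent to background or to the grid exterior).  Nearest-surface distances
use a KD-tree; :func:`pairwise_min_distances_bruteforce` is the exhaustive
O(n·m) reference kept for validation.

Metrics that are undefined for an input (an empty surface, two empty masks)
are reported as NaN "not evaluable" markers with explicit flags — never
silently dropped — because a structure absent from one structure set (new
nodal disease visible only on the replanning CT) is a real failure mode
that must stay visible in cohort reports.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import StructureMask
from .errors import GeometryError, NotEvaluableError, ValidationError

__all__ = [
    "SurfacePointSet",
    "DirectedDistanceSet",
    "GeometricReport",
    "extract_surface",
    "compute_dsc",
    "classify_agreement",
    "directed_distances",
    "pairwise_min_distances_bruteforce",
    "compute_hd",
    "compute_hd95",
    "compute_sdsc",
    "geometric_report",
    "AGREEMENT_BANDS",
]

#: Exact-match tolerance used when τ = 0 mm.
ZERO_TAU_TOL_MM = 1e-6


@dataclass
class SurfacePointSet:
    """Boundary face centers (mm) of one mask's foreground/background interface."""

    points: np.ndarray  # (n, 3) mm
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def is_empty(self) -> bool:
        return len(self) == 0


@dataclass
class DirectedDistanceSet:
    """Per-source-point minimum distances (mm) to the target surface."""

    from_label: str
    to_label: str
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        if np.any(self.distances < 0):
            raise ValidationError("directed distances must be >= 0")


def extract_surface(mask: StructureMask) -> SurfacePointSet:
    """Boundary face centers of a mask, in mm.

    One point per face shared by a foreground and a background voxel of the
    grid, located at the face center.  The surface is nonempty iff the mask
    contains both foreground and background; an all-foreground mask has no
    interface (the grid exterior is not treated as background).
    """
    occ = mask.occupancy.astype(np.int8)
    pts = []
    for axis in range(3):
        # diff[i] sits between voxels i and i+1: nonzero where fg meets bg,
        # so the face plane is at index i + 1/2 along `axis`
        diff = np.diff(occ, axis=axis)
        idx = np.argwhere(diff != 0).astype(float)
        if idx.size:
            idx[:, axis] += 0.5
            pts.append(mask.grid.index_to_mm(idx))
    if not pts:
        return SurfacePointSet(points=np.empty((0, 3)), label=mask.label)
    return SurfacePointSet(points=np.vstack(pts), label=mask.label)


def compute_dsc(a: StructureMask, b: StructureMask) -> float:
    """Volumetric Dice overlap by voxel counts on a shared grid.

    Returns 0.0 if exactly one mask is empty (complete disagreement, e.g. a
    structure missing from one structure set) and NaN if both are empty.
    """
    if not a.grid.same_geometry(b.grid):
        raise GeometryError("DSC requires both masks on one grid")
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        return math.nan
    if na == 0 or nb == 0:
        return 0.0
    inter = int(np.logical_and(a.occupancy, b.occupancy).sum())
    return 2.0 * inter / (na + nb)


#: Qualitative agreement bands for DSC, kappa-style:
#: (lower bound inclusive after rounding to 2 decimals, band name).
AGREEMENT_BANDS: Tuple[Tuple[float, str], ...] = (
    (0.81, "almost perfect"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (0.01, "none to slight"),
    (0.00, "no agreement"),
)


def classify_agreement(dsc: float) -> str:
    """Qualitative agreement band of a DSC value.

    The value is rounded half-up to 2 decimals before banding (the scale is
    quoted to 2 decimals), so 0.205 -> 0.21 -> "fair".  Decimal rounding is
    used so that values printed as 0.205 do not fall to 0.20 through binary
    representation.
    """
    if math.isnan(dsc):
        raise ValidationError("agreement band undefined for not-evaluable DSC")
    if not 0.0 <= dsc <= 1.0:
        raise ValidationError(f"DSC must be in [0, 1], got {dsc}")
    from decimal import ROUND_HALF_UP, Decimal

    r = float(Decimal(repr(dsc)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    for lo, band in AGREEMENT_BANDS:
        if r >= lo:
            return band
    return "no agreement"  # pragma: no cover - unreachable


def directed_distances(
    src: SurfacePointSet, dst: SurfacePointSet
) -> DirectedDistanceSet:
    """Minimum Euclidean distance (mm) from each src point to the dst surface."""
    if dst.is_empty:
        raise NotEvaluableError(
            f"directed distances to empty surface {dst.label!r} are not evaluable"
        )
    if src.is_empty:
        d = np.empty(0)
    else:
        d, _ = cKDTree(dst.points).query(src.points, k=1)
    return DirectedDistanceSet(from_label=src.label, to_label=dst.label, distances=d)


def pairwise_min_distances_bruteforce(
    src: SurfacePointSet, dst: SurfacePointSet
) -> np.ndarray:
    """Exhaustive O(n·m) per-point minimum distances — the validation oracle.

    Kept deliberately naive (full pairwise distance matrix); use only on
    small surfaces.
    """
    if dst.is_empty:
        raise NotEvaluableError("empty target surface")
    diff = src.points[:, None, :] - dst.points[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def _check_surfaces(a: SurfacePointSet, b: SurfacePointSet) -> None:
    if a.is_empty or b.is_empty:
        raise NotEvaluableError(
            f"distance metric not evaluable: empty surface "
            f"({a.label!r}: {len(a)} pts, {b.label!r}: {len(b)} pts)"
        )


def compute_hd(a: SurfacePointSet, b: SurfacePointSet) -> float:
    """Plain (maximum) symmetric Hausdorff distance in mm."""
    _check_surfaces(a, b)
    d_ab = directed_distances(a, b).distances
    d_ba = directed_distances(b, a).distances
    return float(max(d_ab.max(), d_ba.max()))


def compute_hd95(a: SurfacePointSet, b: SurfacePointSet) -> float:
    """95th-percentile Hausdorff distance in mm.

    Convention: linear-interpolation 95th percentile of each directed
    distance set, then the maximum of the two directions (symmetric).
    """
    _check_surfaces(a, b)
    d_ab = directed_distances(a, b).distances
    d_ba = directed_distances(b, a).distances
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def compute_sdsc(a: SurfacePointSet, b: SurfacePointSet, tau: float) -> float:
    """Symmetric surface Dice at tolerance ``tau`` mm (count-weighted)."""
    if tau < 0:
        raise ValidationError(f"tau must be >= 0, got {tau}")
    _check_surfaces(a, b)
    tol = max(tau, ZERO_TAU_TOL_MM)
    d_ab = directed_distances(a, b).distances
    d_ba = directed_distances(b, a).distances
    hits = int((d_ab <= tol).sum()) + int((d_ba <= tol).sum())
    return hits / (len(a) + len(b))


@dataclass
class GeometricReport:
    """Per-structure geometric agreement record.

    Distance metrics that could not be evaluated (an empty surface on either
    side) are NaN with ``evaluable`` False; ``new_structure`` marks the
    clinically meaningful case of a structure present in only one of the two
    structure sets.
    """

    label: str
    role: str
    subset: Optional[str]  # "tumor" | "node" | None
    v_ro_cc: float
    v_dir_cc: float
    dsc: float
    hd_mm: float
    hd95_mm: float
    sdsc: dict  # tau (mm) -> value
    agreement_band: Optional[str]
    evaluable: bool
    new_structure: bool


def _subset_of(role: str) -> Optional[str]:
    if role in ("GTVp", "CTV-T"):
        return "tumor"
    if role in ("GTVn", "CTV-N"):
        return "node"
    return None


def geometric_report(
    ro: StructureMask,
    dir_mask: StructureMask,
    taus: Sequence[float] = (0.0, 2.0),
) -> GeometricReport:
    """All geometric metrics for one physician/DIR structure pair."""
    if not ro.grid.same_geometry(dir_mask.grid):
        raise GeometryError("geometric report requires a shared grid")
    dsc = compute_dsc(ro, dir_mask)
    new_structure = ro.is_empty != dir_mask.is_empty
    surf_ro = extract_surface(ro)
    surf_dir = extract_surface(dir_mask)
    try:
        hd = compute_hd(surf_ro, surf_dir)
        hd95 = compute_hd95(surf_ro, surf_dir)
        sdsc = {float(t): compute_sdsc(surf_ro, surf_dir, t) for t in taus}
        evaluable = True
    except NotEvaluableError:
        hd = hd95 = math.nan
        sdsc = {float(t): math.nan for t in taus}
        evaluable = False
    band = None if math.isnan(dsc) else classify_agreement(dsc)
    return GeometricReport(
        label=ro.label,
        role=ro.role,
        subset=_subset_of(ro.role),
        v_ro_cc=ro.volume_cc,
        v_dir_cc=dir_mask.volume_cc,
        dsc=dsc,
        hd_mm=hd,
        hd95_mm=hd95,
        sdsc=sdsc,
        agreement_band=band,
        evaluable=evaluable,
        new_structure=new_structure,
    )
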