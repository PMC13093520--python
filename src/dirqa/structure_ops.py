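"""Mask-level structure operations.

Contour-to-mask conversion (even-odd rule at voxel centers), isotropic
margin expansion with anisotropic-spacing-aware Euclidean distances
(CTV -> PTV), volume-change bookkeeping, and the grouping of structures
into the tumor / node / PTV analysis sets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .core import (
    ContourSet,
    NODE_ROLES,
    StructureMask,
    TUMOR_ROLES,
    VoxelGrid,
)
from .errors import GeometryError, ValidationError

__all__ = [
    "StructureMask",
    "StructureGrouping",
    "rasterize",
    "contours_from_mask",
    "expand_margin",
    "volume_change",
    "build_grouping",
]


def rasterize(contour_set: ContourSet, grid: VoxelGrid) -> StructureMask:
    """Voxelize planar polygons on ``grid`` by the even-odd rule.

    A voxel is foreground iff its center lies inside an odd number of that
    slice's polygons, so concentric contours carve holes.  Each polygon is
    assigned to the nearest grid slice (ties broken toward the lower index,
    since RTSTRUCT z values rarely land exactly on slice centers); a polygon
    farther than half a slice spacing from every slice raises
    :class:`GeometryError`.
    """
    occ = np.zeros(grid.shape, dtype=bool)
    zs = grid.axis_coords(2)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    for z, verts in contour_set.polygons:
        dist = np.abs(zs - z)
        k = int(np.argmin(dist))  # argmin takes the first (lower) index on ties
        if dist[k] > grid.spacing[2] / 2 + 1e-9:
            raise GeometryError(
                f"structure {contour_set.label!r}: polygon at z={z:g} mm is "
                f"farther than half a slice from every grid slice"
            )
        path = MplPath(verts)
        # contains_points' radius handling depends on vertex orientation;
        # taking the union over +/- radius makes the test closed (boundary
        # points inside) and invariant to vertex order reversal
        inside = path.contains_points(centers, radius=1e-9) | path.contains_points(
            centers, radius=-1e-9
        )
        occ[:, :, k] ^= inside.reshape(len(xs), len(ys))
    return StructureMask(
        label=contour_set.label, role=contour_set.role, grid=grid, occupancy=occ
    )


def contours_from_mask(mask: StructureMask, level: float = 0.5) -> ContourSet:
    """Trace per-slice iso-contours of a mask (for DICOM export)."""
    from skimage import measure

    polygons: List[Tuple[float, np.ndarray]] = []
    zs = mask.grid.axis_coords(2)
    for k in range(mask.grid.shape[2]):
        plane = mask.occupancy[:, :, k].astype(float)
        if not plane.any():
            continue
        padded = np.pad(plane, 1)  # close contours that touch the grid edge
        for ring in measure.find_contours(padded, level):
            idx = ring - 1.0  # undo the pad
            xy = np.column_stack(
                [
                    mask.grid.origin[0] + mask.grid.spacing[0] * idx[:, 0],
                    mask.grid.origin[1] + mask.grid.spacing[1] * idx[:, 1],
                ]
            )
            if xy.shape[0] >= 3:
                polygons.append((float(zs[k]), xy))
    return ContourSet(label=mask.label, role=mask.role, polygons=polygons)


def expand_margin(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic margin expansion: all voxel centers within ``margin_mm``
    (Euclidean, physical spacing) of the input foreground.

    Uses an exact Euclidean distance transform with anisotropic sampling and
    a closed-ball threshold (distance <= margin), so a 3 mm margin on
    2.5 mm slices behaves correctly.  The result's role is "PTV", matching
    the clinical CTV -> PTV step.
    """
    if margin_mm < 0:
        raise ValidationError(f"margin must be >= 0, got {margin_mm}")
    if margin_mm == 0 or mask.is_empty:
        out = mask.occupancy.copy()
    else:
        dist = ndimage.distance_transform_edt(
            ~mask.occupancy, sampling=mask.grid.spacing
        )
        out = dist <= margin_mm + 1e-9
    return StructureMask(label=mask.label, role="PTV", grid=mask.grid, occupancy=out)


def volume_change(v_initial: float, v_replanning: float) -> float:
    """Percent volume change 100*(V_replan - V_initial)/V_initial."""
    if v_initial <= 0:
        raise ValidationError(
            f"volume change undefined for initial volume {v_initial} cm^3"
        )
    return 100.0 * (v_replanning - v_initial) / v_initial


@dataclass
class StructureGrouping:
    """Partition of a structure set into the analysis groups.

    ``combined`` (all GTV and CTV structures, analyzed individually — never a
    geometric union) splits into the disjoint ``tumor`` (GTVp, CTV-T) and
    ``node`` (GTVn, CTV-N) subsets; ``ptv`` is the separate PTV group.
    """

    combined: List[str] = field(default_factory=list)
    tumor: List[str] = field(default_factory=list)
    node: List[str] = field(default_factory=list)
    ptv: List[str] = field(default_factory=list)
    excluded: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.tumor) & set(self.node):
            raise ValidationError("tumor and node subsets must be disjoint")
        if set(self.tumor) | set(self.node) != set(self.combined):
            raise ValidationError("tumor + node must partition the combined set")
        if set(self.ptv) & set(self.combined):
            raise ValidationError("PTV set must be disjoint from GTV+CTV set")


def build_grouping(structures: Iterable[StructureMask]) -> StructureGrouping:
    """Group structures by role; role "other" is excluded with a warning."""
    g = StructureGrouping()
    for s in structures:
        if s.role in TUMOR_ROLES:
            g.tumor.append(s.label)
            g.combined.append(s.label)
        elif s.role in NODE_ROLES:
            g.node.append(s.label)
            g.combined.append(s.label)
        elif s.role == "PTV":
            g.ptv.append(s.label)
        else:
            warnings.warn(f"structure {s.label!r} has role 'other'; excluded")
            g.excluded.append(s.label)
    return g
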