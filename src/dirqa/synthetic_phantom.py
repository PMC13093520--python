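"""Synthetic paired planning/replanning cases.

Emulates the data a head-and-neck offline-replanning study produces, with
fully known ground truth:

* a reference ("initial CT") structure set — an ellipsoidal primary GTV
  plus one or more nodal GTVs, CTVs by margin expansion, PTVs by a further
  3 mm expansion;
* "replanning CT" anatomy obtained by warping those structures with a
  smooth displacement field (affine drift + radial/directional Gaussian
  bumps), giving controllable per-structure volume changes of the
  ±15–25 % magnitude seen clinically (tumor shrinkage/growth, positioning,
  weight loss);
* a "DIR-propagated" copy of each replanning structure perturbed by a
  systematic shift plus a smooth random displacement of amplitude ε — a
  generic surrogate for registration error, controllable but with no claim
  of matching any particular algorithm's error structure;
* conformal dose grids per plan: each dose level contributes its
  prescription inside its PTV and a Gaussian penumbra falloff outside, the
  per-voxel dose being the maximum over levels (a simultaneous-integrated-
  boost-like pattern at 54/56, 60/63 and 70 Gy);
* re-optimization noise: smooth multiplicative fields emulating the
  plan-to-plan variability of the optimizer, with distinct sub-seeds per
  replicate.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so identical parameters + seed give
byte-identical cohorts.  Smooth random fields are seeded white noise
convolved with a Gaussian kernel of the stated correlation length, mean
removed, then amplitude-normalized to the stated maximum.

Mask warping is indicator pull-back with linear interpolation and a 0.5
threshold; nearest-neighbor warping is deliberately avoided because its
stair-casing confounds surface metrics at small ε.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import CaseBundle, DoseGrid, StructureMask, VoxelGrid
from .errors import GeometryError, ValidationError
from .structure_ops import expand_margin, volume_change

__all__ = [
    "PhantomParams",
    "SyntheticCase",
    "make_reference_structures",
    "deform_anatomy",
    "emulate_dir_propagation",
    "make_dose",
    "perturb_dose",
    "make_case",
    "make_cohort",
    "smooth_scalar_field",
    "smooth_vector_field",
    "warp_mask",
    "invert_displacement",
]

#: Clinical dose tiers (Gy) of a simultaneous-integrated-boost plan.
DOSE_LEVELS = (54.0, 56.0, 60.0, 63.0, 70.0)
_NODE_LEVELS = (60.0, 54.0, 63.0, 56.0)  # assigned to nodes in rotation


@dataclass
class DeformationBump:
    """One Gaussian displacement bump: radial (grow/shrink around ``center``)
    or directional (local drift along ``direction``)."""

    center_mm: Tuple[float, float, float]
    width_mm: float
    amplitude_mm: float
    direction: Optional[Tuple[float, float, float]] = None  # None -> radial


@dataclass
class PhantomParams:
    """All knobs of the generator, with study-like defaults.

    Amplitudes of exactly 0 for ``dir_error_amplitude_mm``, ``dir_shift_mm``
    and ``plan_noise_amplitude`` are guaranteed to produce exact duplicates
    (perfect metrics downstream).
    """

    # grid: 112 x 112 x 70 mm at 2 mm in-plane, 2.5 mm slices
    grid_shape: Tuple[int, int, int] = (56, 56, 28)
    grid_spacing: Tuple[float, float, float] = (2.0, 2.0, 2.5)
    grid_origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    # structure primitives
    gtvp_radii_mm: Tuple[float, float, float] = (11.0, 9.0, 8.0)
    gtvp_center_frac: Tuple[float, float, float] = (0.42, 0.5, 0.5)
    n_nodes: int = 2
    node_radius_mm: float = 6.0
    ctv_margin_mm: float = 5.0
    ptv_margin_mm: float = 3.0  # clinical CTV -> PTV expansion
    # anatomy change (initial -> replanning)
    anat_translation_mm: Tuple[float, float, float] = (1.0, 0.5, 0.0)
    anat_bump_width_mm: float = 15.0
    anat_bump_amplitude_mm: float = 0.5  # radial, ~ +-15 % volume on a 10 mm GTV
    # DIR propagation error
    dir_shift_mm: Tuple[float, float, float] = (1.0, 0.5, 0.0)
    dir_error_amplitude_mm: float = 2.0
    dir_corr_length_mm: float = 12.0
    drop_structure: bool = False  # "new nodal disease" scenario
    # dose
    penumbra_sigma_mm: float = 5.0
    # plan (optimizer) noise
    plan_noise_amplitude: float = 0.02
    plan_corr_length_mm: float = 20.0
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dir_error_amplitude_mm < 0 or self.anat_bump_width_mm <= 0:
            raise ValidationError("amplitudes must be >= 0 and widths > 0")
        if not 0 <= self.plan_noise_amplitude < 1:
            raise ValidationError(
                "plan noise amplitude must be in [0, 1) to keep dose nonnegative"
            )
        if self.n_nodes < 0:
            raise ValidationError("n_nodes must be >= 0")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(
            origin=self.grid_origin, spacing=self.grid_spacing, shape=self.grid_shape
        )


@dataclass
class SyntheticCase:
    """One generated case plus the exact ground truth that produced it."""

    bundle: CaseBundle
    anatomy_field_mm: np.ndarray  # (3, *grid.shape), initial -> replanning
    dir_field_mm: np.ndarray  # (3, *grid.shape), replanning -> DIR copy
    volume_changes_pct: Dict[str, float]  # initial -> replanning, per structure
    params: PhantomParams


# ---------------------------------------------------------------------------
# random fields and warping
# ---------------------------------------------------------------------------


def smooth_scalar_field(
    grid: VoxelGrid, corr_length_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean smooth field with max |value| = 1 (white noise * Gaussian)."""
    noise = rng.standard_normal(grid.shape)
    sigma_vox = [corr_length_mm / s for s in grid.spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    f -= f.mean()
    peak = np.abs(f).max()
    if peak == 0:
        return f
    return f / peak


def smooth_vector_field(
    grid: VoxelGrid, corr_length_mm: float, amplitude_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth displacement field (3, *shape) mm with max magnitude = amplitude."""
    comps = np.stack(
        [
            ndimage.gaussian_filter(
                rng.standard_normal(grid.shape),
                sigma=[corr_length_mm / s for s in grid.spacing],
                mode="wrap",
            )
            for _ in range(3)
        ]
    )
    comps -= comps.mean(axis=(1, 2, 3), keepdims=True)
    mag = np.sqrt((comps**2).sum(axis=0)).max()
    if mag == 0 or amplitude_mm == 0:
        return np.zeros_like(comps)
    return comps * (amplitude_mm / mag)


def _bump_field(grid: VoxelGrid, bumps: Sequence[DeformationBump]) -> np.ndarray:
    centers = grid.voxel_centers().reshape(*grid.shape, 3)
    u = np.zeros((3,) + grid.shape)
    for b in bumps:
        delta = centers - np.asarray(b.center_mm)
        r2 = (delta**2).sum(axis=-1)
        w = np.exp(-r2 / (2.0 * b.width_mm**2))
        if b.direction is None:  # radial: expansion (a>0) / contraction (a<0)
            r = np.sqrt(r2)
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(r[..., None] > 1e-9, delta / r[..., None], 0.0)
            vec = unit * (b.amplitude_mm * w)[..., None]
        else:
            d = np.asarray(b.direction, dtype=float)
            d = d / np.linalg.norm(d)
            vec = d[None, None, None, :] * (b.amplitude_mm * w)[..., None]
        u += vec.transpose(3, 0, 1, 2)
    return u


def warp_mask(mask: StructureMask, field_mm: np.ndarray) -> StructureMask:
    """Pull-back warp of a binary mask by a displacement field in mm.

    ``out(x) = in(x - u(x))`` with linear interpolation of the indicator and
    a 0.5 threshold, so a radially outward field grows the structure.
    Raises :class:`GeometryError` if the (approximate forward) displacement
    carries any foreground voxel outside the grid.
    """
    if field_mm.shape != (3,) + mask.grid.shape:
        raise GeometryError("displacement field shape must be (3, *grid.shape)")
    spacing = np.asarray(mask.grid.spacing).reshape(3, 1, 1, 1)
    idx = np.indices(mask.grid.shape).astype(float)
    if np.any(field_mm) and not mask.is_empty:
        # forward map x + u(x) of the foreground voxel centers
        fwd = (idx + field_mm / spacing)[:, mask.occupancy]
        upper = np.asarray(mask.grid.shape).reshape(3, 1) - 0.5
        if np.any(fwd < -0.5) or np.any(fwd > upper):
            raise GeometryError(
                f"structure {mask.label!r}: displacement carries foreground "
                "outside the grid"
            )
    coords = idx - field_mm / spacing
    warped = ndimage.map_coordinates(
        mask.occupancy.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    occ = warped >= 0.5
    return StructureMask(
        label=mask.label, role=mask.role, grid=mask.grid, occupancy=occ
    )


def invert_displacement(
    field_mm: np.ndarray, grid: VoxelGrid, n_iter: int = 25
) -> np.ndarray:
    """Approximate inverse displacement by fixed-point iteration.

    Solves v(x) = -u(x + v(x)); warping by ``v`` approximately undoes a warp
    by ``u``.
    """
    spacing = np.asarray(grid.spacing).reshape(3, 1, 1, 1)
    idx = np.indices(grid.shape).astype(float)
    v = np.zeros_like(field_mm)
    for _ in range(n_iter):
        coords = idx + v / spacing
        u_at = np.stack(
            [
                ndimage.map_coordinates(field_mm[c], coords, order=1, mode="nearest")
                for c in range(3)
            ]
        )
        v = -u_at
    return v


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def _ellipsoid(
    grid: VoxelGrid, center_mm: Sequence[float], radii_mm: Sequence[float],
    label: str, role: str,
) -> StructureMask:
    centers = grid.voxel_centers().reshape(*grid.shape, 3)
    norm = ((centers - np.asarray(center_mm)) / np.asarray(radii_mm)) ** 2
    return StructureMask(
        label=label, role=role, grid=grid, occupancy=norm.sum(axis=-1) <= 1.0
    )


def make_reference_structures(
    params: PhantomParams, rng: Optional[np.random.Generator] = None
) -> Dict[str, StructureMask]:
    """Reference ("initial CT") GTV/CTV/PTV set on the phantom grid.

    GTVs are voxelized ellipsoids; each CTV is its GTV expanded by the CTV
    margin; each PTV is its CTV expanded by the PTV margin (3 mm default).
    Node positions are drawn around the primary unless ``rng`` is None, in
    which case a deterministic lattice of offsets is used.
    """
    grid = params.grid
    extent = np.asarray(grid.spacing) * (np.asarray(grid.shape) - 1)
    gtvp_center = np.asarray(grid.origin) + extent * np.asarray(
        params.gtvp_center_frac
    )
    total_margin = params.ctv_margin_mm + params.ptv_margin_mm
    if np.any(np.asarray(params.gtvp_radii_mm) + total_margin >= extent / 2):
        raise ValidationError("primary GTV (plus margins) does not fit the grid")
    structures: Dict[str, StructureMask] = {}
    structures["GTVp"] = _ellipsoid(
        grid, gtvp_center, params.gtvp_radii_mm, "GTVp", "GTVp"
    )
    # node offsets stay mostly in-plane: head-and-neck nodal levels sit
    # lateral to the primary, and axial grids are short in z
    node_dirs = np.array(
        [(1.0, 0.8, 0.15), (1.0, -0.8, -0.15), (0.95, -0.1, 0.3), (0.8, 0.5, -0.3)]
    )
    gap = max(params.gtvp_radii_mm) + params.node_radius_mm + total_margin + 6.0
    for i in range(params.n_nodes):
        d = node_dirs[i % len(node_dirs)]
        d = d / np.linalg.norm(d)
        if rng is not None:
            d = d + rng.normal(scale=0.08, size=3)
            d = d / np.linalg.norm(d)
        center = gtvp_center + d * gap
        lo = np.asarray(grid.origin) + params.node_radius_mm + total_margin
        hi = np.asarray(grid.origin) + extent - params.node_radius_mm - total_margin
        if np.any(lo > hi):
            raise ValidationError(f"node {i} (plus margins) does not fit the grid")
        center = np.clip(center, lo, hi)  # keep drawn nodes inside the grid
        r = params.node_radius_mm
        structures[f"GTVn{i + 1}"] = _ellipsoid(
            grid, center, (r, r, r * 0.9), f"GTVn{i + 1}", "GTVn"
        )
    for label in list(structures):
        gtv = structures[label]
        ctv_label = "CTV-T" if label == "GTVp" else f"CTV-N{label[4:]}"
        ctv = expand_margin(gtv, params.ctv_margin_mm)
        ctv.label, ctv.role = ctv_label, "CTV-T" if label == "GTVp" else "CTV-N"
        structures[ctv_label] = ctv
    for ctv_label in [l for l in structures if l.startswith("CTV")]:
        ptv = expand_margin(structures[ctv_label], params.ptv_margin_mm)
        ptv.label = "PTV-" + ctv_label.split("-", 1)[1]
        structures[ptv.label] = ptv
    return structures


def _node_id(label: str) -> Optional[str]:
    m = re.match(r"^(?:GTVn|CTV-N|PTV-N)(\d+)$", label)
    return m.group(1) if m else None


def default_prescriptions(structures: Dict[str, StructureMask]) -> Dict[str, float]:
    """Dose level per structure: 70 Gy for the tumor chain, rotating nodal tiers."""
    out: Dict[str, float] = {}
    node_ids = sorted({nid for l in structures if (nid := _node_id(l)) is not None})
    level_of_node = {
        nid: _NODE_LEVELS[i % len(_NODE_LEVELS)] for i, nid in enumerate(node_ids)
    }
    for label in structures:
        if label in ("GTVp", "CTV-T", "PTV-T"):
            out[label] = 70.0
        else:
            nid = _node_id(label)
            if nid in level_of_node:
                out[label] = level_of_node[nid]
    return out


def _gtv_ctv(structures: Dict[str, StructureMask]) -> Dict[str, StructureMask]:
    return {
        l: m for l, m in structures.items() if m.role in ("GTVp", "GTVn", "CTV-T", "CTV-N")
    }


def regenerate_ptvs(
    structures: Dict[str, StructureMask], ptv_margin_mm: float
) -> Dict[str, StructureMask]:
    """CTV -> PTV expansion for every CTV in a structure set (in place copy)."""
    out = dict(_gtv_ctv(structures))
    for label, m in list(out.items()):
        if label.startswith("CTV"):
            ptv = expand_margin(m, ptv_margin_mm)
            ptv.label = "PTV-" + label.split("-", 1)[1]
            out[ptv.label] = ptv
    return out


def deform_anatomy(
    structures: Dict[str, StructureMask],
    params: PhantomParams,
    rng: np.random.Generator,
    bumps: Optional[Sequence[DeformationBump]] = None,
) -> Tuple[Dict[str, StructureMask], np.ndarray, Dict[str, float]]:
    """Warp a structure set into its "replanning CT" version.

    The displacement is a uniform translation plus Gaussian bumps (default:
    one radial bump on the primary GTV — growth/shrinkage — and one
    directional bump near the nodes — positioning change).  GTVs and CTVs
    are warped; PTVs are regenerated from the warped CTVs afterwards.
    Returns ``(warped structures, field mm, achieved volume changes %)``.
    """
    grid = next(iter(structures.values())).grid
    if bumps is None:
        gtvp = structures.get("GTVp")
        bumps = []
        if gtvp is not None and not gtvp.is_empty:
            bumps.append(
                DeformationBump(
                    center_mm=tuple(gtvp.centroid_mm()),
                    width_mm=params.anat_bump_width_mm,
                    amplitude_mm=params.anat_bump_amplitude_mm,
                )
            )
        nodes = [m for l, m in structures.items() if l.startswith("GTVn")]
        if nodes and not nodes[0].is_empty:
            direction = tuple(rng.normal(size=3))
            bumps.append(
                DeformationBump(
                    center_mm=tuple(nodes[0].centroid_mm()),
                    width_mm=params.anat_bump_width_mm,
                    amplitude_mm=0.6 * abs(params.anat_bump_amplitude_mm),
                    direction=direction,
                )
            )
    field = _bump_field(grid, bumps)
    field += np.asarray(params.anat_translation_mm).reshape(3, 1, 1, 1)
    warped: Dict[str, StructureMask] = {}
    changes: Dict[str, float] = {}
    for label, m in _gtv_ctv(structures).items():
        w = warp_mask(m, field)
        warped[label] = w
        if not m.is_empty:
            changes[label] = volume_change(m.volume_cc, w.volume_cc)
    warped = regenerate_ptvs(warped, params.ptv_margin_mm)
    return warped, field, changes


def emulate_dir_propagation(
    replanning: Dict[str, StructureMask],
    params: PhantomParams,
    rng: np.random.Generator,
) -> Tuple[Dict[str, StructureMask], np.ndarray, Optional[str]]:
    """Perturb the replanning set into its "DIR-propagated" copy.

    The perturbation is a systematic shift plus a smooth random displacement
    of amplitude ε (``dir_error_amplitude_mm``); with both zero the copy is
    exact.  When ``params.drop_structure`` is set, the last nodal chain is
    emptied in the DIR set — the "new nodal disease present only on the
    replanning CT" failure that propagation cannot recreate.  Returns
    ``(dir structures, field mm, dropped label or None)``.
    """
    grid = next(iter(replanning.values())).grid
    field = smooth_vector_field(
        grid, params.dir_corr_length_mm, params.dir_error_amplitude_mm, rng
    )
    field += np.asarray(params.dir_shift_mm).reshape(3, 1, 1, 1)
    dropped = None
    if params.drop_structure:
        node_labels = sorted(l for l in replanning if l.startswith("GTVn"))
        if node_labels:
            dropped = node_labels[-1]
    out: Dict[str, StructureMask] = {}
    for label, m in _gtv_ctv(replanning).items():
        if dropped is not None and label.endswith(dropped[4:]) and (
            label.startswith("GTVn") or label.startswith("CTV-N")
        ):
            out[label] = StructureMask(
                label=label, role=m.role, grid=grid,
                occupancy=np.zeros(grid.shape, dtype=bool),
            )
            continue
        out[label] = warp_mask(m, field)
    out = regenerate_ptvs(out, params.ptv_margin_mm)
    return out, field, dropped


# ---------------------------------------------------------------------------
# dose
# ---------------------------------------------------------------------------


def make_dose(
    ptvs: Dict[str, StructureMask],
    prescriptions: Dict[str, float],
    grid: VoxelGrid,
    penumbra_sigma_mm: float = 5.0,
) -> DoseGrid:
    """Conformal dose: per-voxel max over levels of prescription x falloff.

    Each dose level contributes its prescription inside its PTV and a
    Gaussian penumbra ``exp(-d^2 / 2 sigma^2)`` of the Euclidean distance
    ``d`` outside it; sigma -> 0 degenerates to a binary dose.  By
    construction the dose inside each PTV is >= its prescription.
    """
    ptv_labels = [l for l in ptvs if l.startswith("PTV")]
    if not ptv_labels:
        raise ValidationError("dose synthesis requires at least one PTV")
    dose = np.zeros(grid.shape)
    for label in ptv_labels:
        if label not in prescriptions:
            raise ValidationError(f"no prescription for PTV {label!r}")
        m = ptvs[label]
        if m.is_empty:
            continue
        p = prescriptions[label]
        dist = ndimage.distance_transform_edt(~m.occupancy, sampling=grid.spacing)
        if penumbra_sigma_mm <= 0:
            level = np.where(m.occupancy, p, 0.0)
        else:
            level = p * np.exp(-(dist**2) / (2.0 * penumbra_sigma_mm**2))
        dose = np.maximum(dose, level)
    return DoseGrid(grid=grid, values=dose)


def perturb_dose(
    dose: DoseGrid,
    amplitude: float,
    corr_length_mm: float,
    rng: np.random.Generator,
) -> DoseGrid:
    """Multiplicative smooth noise ``dose * (1 + eta)``, |eta| <= amplitude.

    Emulates re-optimization variability; ``eta`` is zero-mean, so total
    dose is preserved up to the field's sampling error.
    """
    if not 0 <= amplitude < 1:
        raise ValidationError(
            f"plan noise amplitude must be in [0, 1), got {amplitude}"
        )
    if amplitude == 0:
        return DoseGrid(grid=dose.grid, values=dose.values.copy())
    eta = amplitude * smooth_scalar_field(dose.grid, corr_length_mm, rng)
    return DoseGrid(grid=dose.grid, values=dose.values * (1.0 + eta))


# ---------------------------------------------------------------------------
# cases and cohorts
# ---------------------------------------------------------------------------


def make_case(
    params: PhantomParams, case_id: str = "case-0"
) -> SyntheticCase:
    """One complete synthetic case from ``params`` (seed included)."""
    ss = np.random.SeedSequence(params.seed)
    s_ref, s_anat, s_dir, s_dose = ss.spawn(4)
    rng_ref = np.random.default_rng(s_ref)
    reference = make_reference_structures(params, rng_ref)
    ro, anat_field, changes = deform_anatomy(
        reference, params, np.random.default_rng(s_anat)
    )
    dir_set, dir_field, dropped = emulate_dir_propagation(
        ro, params, np.random.default_rng(s_dir)
    )
    prescriptions = default_prescriptions(reference)
    grid = params.grid
    dose_rngs = np.random.default_rng(s_dose).spawn(2 + params.n_replicates)
    base_ro = make_dose(ro, prescriptions, grid, params.penumbra_sigma_mm)
    base_dir = make_dose(dir_set, prescriptions, grid, params.penumbra_sigma_mm)
    doses = {
        "RO": perturb_dose(
            base_ro, params.plan_noise_amplitude, params.plan_corr_length_mm,
            dose_rngs[0],
        ),
        "DIR": perturb_dose(
            base_dir, params.plan_noise_amplitude, params.plan_corr_length_mm,
            dose_rngs[1],
        ),
    }
    for r in range(params.n_replicates):
        doses[f"RO_rep{r}"] = perturb_dose(
            base_ro, params.plan_noise_amplitude, params.plan_corr_length_mm,
            dose_rngs[2 + r],
        )
    bundle = CaseBundle(
        case_id=case_id,
        grid=grid,
        structures={"RO": ro, "DIR": dir_set, "REF": reference},
        doses=doses,
        prescriptions=prescriptions,
        meta={
            "seed": int(params.seed),
            "dropped_structure": dropped,
            "volume_changes_pct": {k: float(v) for k, v in changes.items()},
        },
    )
    return SyntheticCase(
        bundle=bundle,
        anatomy_field_mm=anat_field,
        dir_field_mm=dir_field,
        volume_changes_pct=changes,
        params=params,
    )


def make_cohort(
    n_patients: int,
    template: Optional[PhantomParams] = None,
    seed: int = 0,
    drop_structure_case: Optional[int] = None,
) -> List[SyntheticCase]:
    """A cohort of cases with per-case parameter draws around ``template``.

    Per case: the radial bump amplitude is drawn uniformly in
    ±|template.anat_bump_amplitude_mm| * 1.6 (a mix of shrinkage and growth
    spanning Table-1-like volume changes), the translation uniformly in
    ±2 mm per axis, the node count in {1, 2, 3}, and the DIR shift direction
    uniformly with magnitude drawn in [0.5, 1.5] * |template shift|.  All
    sub-seeds derive from ``seed``; the same seed reproduces the cohort
    byte-identically.  ``drop_structure_case`` selects one case index for
    the "new nodal disease" scenario.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    base = template if template is not None else PhantomParams()
    child_seeds = np.random.SeedSequence(seed).spawn(n_patients)
    cases: List[SyntheticCase] = []
    for i, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        amp = float(rng.uniform(-1.6, 1.6) * abs(base.anat_bump_amplitude_mm))
        trans = tuple(float(v) for v in rng.uniform(-2.0, 2.0, size=3))
        n_nodes = int(rng.integers(1, 4))
        shift_mag = np.linalg.norm(base.dir_shift_mm)
        if shift_mag > 0:
            d = rng.normal(size=3)
            d = d / np.linalg.norm(d)
            shift = tuple(float(v) for v in d * shift_mag * rng.uniform(0.5, 1.5))
        else:
            shift = (0.0, 0.0, 0.0)
        params = replace(
            base,
            anat_bump_amplitude_mm=amp,
            anat_translation_mm=trans,
            n_nodes=n_nodes,
            dir_shift_mm=shift,
            drop_structure=(i == drop_structure_case),
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        cases.append(make_case(params, case_id=f"case-{i}"))
    return cases
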