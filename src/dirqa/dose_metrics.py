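"""DVH and spatial dose-difference metrics.

DVH summaries use sample sorting with linear interpolation (no dose
binning): D95%/D50% are the 5th/50th linear-interpolation percentiles of
the per-voxel doses inside a structure — the minimum dose received by the
hottest 95%/50% of the volume — and Dmax is the maximum evaluated voxel
dose (no near-max volume qualifier).  V95% is the fraction of the structure
receiving at least 95% of its prescription; a structure "passes" coverage
when V95% >= 0.95.

The spatial dose-difference (DD) pass rate compares two plans voxel by
voxel inside an evaluation mask Ω defined by the physician (RO) structure:
Δ(x) = (D_DIR(x) − D_RO(x)) / D_RO(x), and DD_τ is the percentage of
evaluated voxels with |Δ(x)| ≤ τ.  The absolute value matters — a signed
criterion would trivially pass every cold spot — but the signed variant is
available behind a flag for sensitivity checks.  Voxels with reference dose
below a low-dose guard (default 0.5 Gy, for division stability) or whose
centers fall outside a dose grid are excluded and counted.

Both dose grids are interpolated (trilinearly) to the Ω structure's grid,
never the reverse, since Ω defines the evaluation domain.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import DoseGrid, StructureMask
from .errors import NotEvaluableError, ValidationError

__all__ = [
    "DVHSummary",
    "DoseDifferenceResult",
    "sample_dose",
    "dvh_summary",
    "cumulative_dvh",
    "relative_dvh_difference",
    "dd_pass_rates",
    "success_rate",
]

#: Default reference-dose floor (Gy) below which Δ(x) is not evaluated.
DEFAULT_LOW_DOSE_GUARD_GY = 0.5


def sample_dose(dose: DoseGrid, mask: StructureMask) -> Tuple[np.ndarray, int]:
    """Trilinear dose samples at the mask's foreground voxel centers.

    Returns ``(samples, n_excluded)`` where excluded voxels are those whose
    centers fall outside the dose grid's support.  When the two grids share
    geometry the samples equal the stored voxel values exactly (linear
    interpolation is exact at nodes).
    """
    if mask.is_empty:
        raise ValidationError(f"cannot sample dose for empty mask {mask.label!r}")
    pts = mask.grid.voxel_centers(mask.occupancy)
    interp = RegularGridInterpolator(
        tuple(dose.grid.axis_coords(a) for a in range(3)),
        dose.values,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    vals = interp(pts)
    inside = np.isfinite(vals)
    return vals[inside], int((~inside).sum())


@dataclass
class DVHSummary:
    """Point summary of one structure's dose-volume histogram."""

    label: str
    plan_id: str
    prescription_gy: float
    d95_gy: float
    d50_gy: float
    dmax_gy: float
    v95_fraction: float

    @property
    def v95_pass(self) -> bool:
        return self.v95_fraction >= 0.95


def dvh_summary(
    samples: np.ndarray,
    prescription_gy: float,
    label: str = "",
    plan_id: str = "",
) -> DVHSummary:
    """DVH point metrics from per-voxel dose samples."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValidationError("DVH summary requires at least one dose sample")
    if prescription_gy <= 0:
        raise ValidationError(f"prescription must be > 0, got {prescription_gy}")
    return DVHSummary(
        label=label,
        plan_id=plan_id,
        prescription_gy=float(prescription_gy),
        d95_gy=float(np.percentile(samples, 5)),
        d50_gy=float(np.percentile(samples, 50)),
        dmax_gy=float(samples.max()),
        v95_fraction=float(np.mean(samples >= 0.95 * prescription_gy)),
    )


def cumulative_dvh(
    samples: np.ndarray, n_points: int = 101
) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH curve: (dose Gy, fraction of volume receiving >= dose)."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValidationError("empty dose samples")
    doses = np.linspace(0.0, samples.max(), n_points)
    frac = np.array([(samples >= d).mean() for d in doses])
    return doses, frac


def relative_dvh_difference(ro: DVHSummary, dir_: DVHSummary) -> Dict[str, float]:
    """Percent plan-to-plan differences 100*(DIR − RO)/RO for d95/d50/dmax.

    A zero reference metric yields NaN (not evaluable) for that entry.
    """
    if ro.label != dir_.label or ro.prescription_gy != dir_.prescription_gy:
        raise ValidationError(
            "relative DVH difference requires the same structure and prescription"
        )
    out: Dict[str, float] = {}
    for name in ("d95_gy", "d50_gy", "dmax_gy"):
        a, b = getattr(ro, name), getattr(dir_, name)
        key = name.replace("_gy", "_rel_pct")
        out[key] = math.nan if a == 0 else 100.0 * (b - a) / a
    return out


@dataclass
class DoseDifferenceResult:
    """Spatial dose-difference pass rates over one evaluation mask Ω."""

    label: str
    deltas: np.ndarray  # per evaluated voxel, dimensionless
    pass_rates_pct: Dict[float, float]  # tau (fraction) -> percent
    n_evaluated: int
    n_excluded: int

    def __post_init__(self) -> None:
        taus = sorted(self.pass_rates_pct)
        rates = [self.pass_rates_pct[t] for t in taus]
        if any(b < a - 1e-9 for a, b in zip(rates, rates[1:])):
            raise ValidationError("pass rate must be nondecreasing in tau")


def dd_pass_rates(
    dose_ro: DoseGrid,
    dose_dir: DoseGrid,
    omega: StructureMask,
    taus: Sequence[float] = (0.02, 0.05),
    low_dose_guard_gy: float = DEFAULT_LOW_DOSE_GUARD_GY,
    signed: bool = False,
) -> DoseDifferenceResult:
    """DD_τ pass rates of ``dose_dir`` vs ``dose_ro`` inside ``omega``.

    ``taus`` are fractional thresholds (0.02 = 2%).  ``signed=True`` uses the
    one-sided criterion Δ(x) ≤ τ instead of |Δ(x)| ≤ τ.
    """
    if omega.is_empty:
        raise ValidationError(f"evaluation mask {omega.label!r} is empty")
    if any(t <= 0 for t in taus):
        raise ValidationError(f"taus must be positive, got {list(taus)}")
    ro_vals, excl_ro = sample_dose(dose_ro, omega)
    dir_vals, excl_dir = sample_dose(dose_dir, omega)
    if excl_ro != excl_dir or ro_vals.size != dir_vals.size:
        # grids differ in support: evaluate on the intersection
        pts = omega.grid.voxel_centers(omega.occupancy)
        ro_i = RegularGridInterpolator(
            tuple(dose_ro.grid.axis_coords(a) for a in range(3)),
            dose_ro.values, bounds_error=False, fill_value=np.nan)
        dir_i = RegularGridInterpolator(
            tuple(dose_dir.grid.axis_coords(a) for a in range(3)),
            dose_dir.values, bounds_error=False, fill_value=np.nan)
        ro_all, dir_all = ro_i(pts), dir_i(pts)
        inside = np.isfinite(ro_all) & np.isfinite(dir_all)
        ro_vals, dir_vals = ro_all[inside], dir_all[inside]
        n_outside = int((~inside).sum())
    else:
        n_outside = excl_ro
    guard = ro_vals >= low_dose_guard_gy
    n_excluded = n_outside + int((~guard).sum())
    ro_vals, dir_vals = ro_vals[guard], dir_vals[guard]
    if ro_vals.size == 0:
        raise NotEvaluableError(
            f"all voxels of {omega.label!r} excluded (outside grid or below "
            f"{low_dose_guard_gy} Gy)"
        )
    deltas = (dir_vals - ro_vals) / ro_vals
    crit = deltas if signed else np.abs(deltas)
    rates = {
        float(t): 100.0 * float((crit <= t + 1e-12).mean()) for t in taus
    }
    return DoseDifferenceResult(
        label=omega.label,
        deltas=deltas,
        pass_rates_pct=rates,
        n_evaluated=int(ro_vals.size),
        n_excluded=n_excluded,
    )


def success_rate(passes: Iterable[Optional[bool]]) -> float:
    """Percent of evaluable (non-None) flags that are True; NaN if none."""
    flags = [p for p in passes if p is not None]
    if not flags:
        return math.nan
    return 100.0 * sum(bool(p) for p in flags) / len(flags)
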