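"""Study orchestration: geometric, dosimetric and reproducibility analysis
over a cohort of case bundles, with CSV/JSON report emission.

Every convention knob (HD95 dialect, percentile method, sDSC denominator,
absolute vs. signed dose-difference criterion, low-dose guard) lives in
:class:`RunConfig` and is echoed verbatim into the run manifest, so a report
is interpretable without the code and regenerating with the same manifest
reproduces it byte-identically.
"""
from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .core import CaseBundle, StructureMask
from .cohort_stats import (
    MetricDistribution,
    build_reproducibility_pairs,
    compare_variability,
    mann_whitney_u,
    pearson,
    summarize,
)
from .dose_metrics import (
    dd_pass_rates,
    dvh_summary,
    relative_dvh_difference,
    sample_dose,
    success_rate,
)
from .errors import DirqaError, NotEvaluableError, ValidationError
from .geometry_metrics import geometric_report
from .structure_ops import build_grouping

__all__ = ["RunConfig", "StudyReport", "run_geometric", "run_dosimetric",
           "run_reproducibility", "run_all", "write_report"]

GEOM_METRICS = ("dsc", "hd95_mm", "sdsc_0mm", "sdsc_2mm")


@dataclass
class RunConfig:
    """All run-time conventions and thresholds of one study replication."""

    sdsc_taus_mm: Tuple[float, ...] = (0.0, 2.0)
    dd_taus: Tuple[float, ...] = (0.02, 0.05)
    ptv_margin_mm: float = 3.0
    low_dose_guard_gy: float = 0.5
    signed_dd: bool = False
    seed: int = 0
    # documentation-only convention strings, echoed into every manifest
    hd95_convention: str = "95th percentile per direction, max of directions"
    percentile_method: str = "linear interpolation between order statistics"
    sdsc_denominator: str = "surface element counts (|RO| + |DIR|)"
    volume_convention: str = "voxelized mask volumes (voxel count x voxel volume)"

    def manifest(self) -> Dict[str, object]:
        d = dataclasses.asdict(self)
        d["software_version"] = __version__
        return d


@dataclass
class StudyReport:
    geometric_rows: pd.DataFrame
    geometric_summaries: Dict[str, Dict[str, MetricDistribution]]
    tumor_vs_node: Dict[str, object]
    correlations: Dict[str, object]
    dvh_rows: pd.DataFrame
    dd_rows: pd.DataFrame
    dose_summaries: Dict[str, object]
    repro_rows: pd.DataFrame
    study_vs_optimizer: Dict[str, object]
    manifest: Dict[str, object]
    warnings_: List[str] = field(default_factory=list)


def _matched_pairs(
    bundle: CaseBundle,
) -> List[Tuple[StructureMask, StructureMask]]:
    """Label-matched (RO, DIR) GTV/CTV structure pairs of one case."""
    ro = bundle.structures.get("RO", {})
    dir_ = bundle.structures.get("DIR", {})
    pairs = []
    for label in sorted(set(ro) | set(dir_)):
        a, b = ro.get(label), dir_.get(label)
        if a is None or b is None:
            continue
        if a.role in ("GTVp", "GTVn", "CTV-T", "CTV-N"):
            pairs.append((a, b))
    return pairs


def run_geometric(bundles: Sequence[CaseBundle], config: RunConfig) -> Dict:
    """Per-structure geometric metrics + cohort summaries, tests, correlations."""
    rows = []
    collected_warnings: List[str] = []
    for bundle in bundles:
        vol_changes = bundle.meta.get("volume_changes_pct", {})
        ro_labels = set(bundle.structures.get("RO", {}))
        dir_labels = set(bundle.structures.get("DIR", {}))
        for missing in sorted(ro_labels ^ dir_labels):
            collected_warnings.append(
                f"{bundle.case_id}: structure {missing!r} present in only one set"
            )
        for ro, dir_mask in _matched_pairs(bundle):
            rep = geometric_report(ro, dir_mask, taus=config.sdsc_taus_mm)
            rows.append(
                {
                    "case_id": bundle.case_id,
                    "label": rep.label,
                    "role": rep.role,
                    "subset": rep.subset,
                    "v_ro_cc": rep.v_ro_cc,
                    "v_dir_cc": rep.v_dir_cc,
                    "dsc": rep.dsc,
                    "hd_mm": rep.hd_mm,
                    "hd95_mm": rep.hd95_mm,
                    **{
                        f"sdsc_{t:g}mm": v for t, v in rep.sdsc.items()
                    },
                    "agreement_band": rep.agreement_band,
                    "evaluable": rep.evaluable,
                    "new_structure": rep.new_structure,
                    "volume_change_pct": vol_changes.get(rep.label, math.nan),
                }
            )
    df = pd.DataFrame(rows)
    summaries: Dict[str, Dict[str, MetricDistribution]] = {}
    tests: Dict[str, object] = {}
    corrs: Dict[str, object] = {}
    if not df.empty:
        sid = df["case_id"] + "/" + df["label"]
        metric_cols = [c for c in GEOM_METRICS if c in df.columns]
        for group, sel in (
            ("combined", np.ones(len(df), dtype=bool)),
            ("tumor", (df["subset"] == "tumor").to_numpy()),
            ("node", (df["subset"] == "node").to_numpy()),
        ):
            summaries[group] = {}
            for m in metric_cols:
                vals = dict(zip(sid[sel], df.loc[sel, m]))
                if vals:
                    try:
                        summaries[group][m] = summarize(vals, group=group)
                    except NotEvaluableError:
                        pass
        for m in metric_cols:
            t = df.loc[(df["subset"] == "tumor") & df[m].notna(), m]
            n = df.loc[(df["subset"] == "node") & df[m].notna(), m]
            if len(t) and len(n):
                tests[m] = mann_whitney_u(t, n, name=f"tumor vs node: {m}")
            ok = df[m].notna() & df["volume_change_pct"].notna()
            if ok.sum() >= 3:
                try:
                    corrs[m] = pearson(
                        df.loc[ok, "volume_change_pct"], df.loc[ok, m]
                    )
                except NotEvaluableError:
                    pass
    return {
        "rows": df,
        "summaries": summaries,
        "tumor_vs_node": tests,
        "correlations": corrs,
        "warnings": collected_warnings,
    }


def _dose_groups(bundle: CaseBundle) -> Dict[str, List[StructureMask]]:
    """RO structures grouped into the two dosimetric categories."""
    ro = bundle.structures.get("RO", {})
    grouping = build_grouping(ro.values())
    return {
        "GTV+CTV": [ro[l] for l in grouping.combined],
        "PTV": [ro[l] for l in grouping.ptv],
    }


def run_dosimetric(bundles: Sequence[CaseBundle], config: RunConfig) -> Dict:
    """DVH differences, V95 success rates and DD pass rates on RO structures."""
    dvh_rows, dd_rows = [], []
    for bundle in bundles:
        if "RO" not in bundle.doses or "DIR" not in bundle.doses:
            raise ValidationError(f"{bundle.case_id}: missing RO or DIR dose grid")
        d_ro, d_dir = bundle.doses["RO"], bundle.doses["DIR"]
        for group, structs in _dose_groups(bundle).items():
            for s in structs:
                if s.is_empty:
                    continue
                presc = bundle.prescriptions.get(s.label)
                if presc is None:
                    continue
                ro_samples, _ = sample_dose(d_ro, s)
                dir_samples, _ = sample_dose(d_dir, s)
                ro_sum = dvh_summary(ro_samples, presc, s.label, "RO")
                dir_sum = dvh_summary(dir_samples, presc, s.label, "DIR")
                rel = relative_dvh_difference(ro_sum, dir_sum)
                dvh_rows.append(
                    {
                        "case_id": bundle.case_id,
                        "label": s.label,
                        "group": group,
                        "prescription_gy": presc,
                        "ro_d95_gy": ro_sum.d95_gy,
                        "ro_d50_gy": ro_sum.d50_gy,
                        "ro_dmax_gy": ro_sum.dmax_gy,
                        "dir_d95_gy": dir_sum.d95_gy,
                        "dir_d50_gy": dir_sum.d50_gy,
                        "dir_dmax_gy": dir_sum.dmax_gy,
                        **rel,
                        "ro_v95_fraction": ro_sum.v95_fraction,
                        "dir_v95_fraction": dir_sum.v95_fraction,
                        "ro_v95_pass": ro_sum.v95_pass,
                        "dir_v95_pass": dir_sum.v95_pass,
                    }
                )
                dd = dd_pass_rates(
                    d_ro, d_dir, s, taus=config.dd_taus,
                    low_dose_guard_gy=config.low_dose_guard_gy,
                    signed=config.signed_dd,
                )
                dd_rows.append(
                    {
                        "case_id": bundle.case_id,
                        "label": s.label,
                        "group": group,
                        **{
                            f"dd_{100 * t:g}pct": dd.pass_rates_pct[t]
                            for t in config.dd_taus
                        },
                        "n_evaluated": dd.n_evaluated,
                        "n_excluded": dd.n_excluded,
                    }
                )
    dvh_df, dd_df = pd.DataFrame(dvh_rows), pd.DataFrame(dd_rows)
    summaries: Dict[str, object] = {}
    for group in ("GTV+CTV", "PTV"):
        gsel = dvh_df["group"] == group if not dvh_df.empty else None
        if gsel is None or not gsel.any():
            continue
        sub = dvh_df[gsel]
        sid = sub["case_id"] + "/" + sub["label"]
        entry: Dict[str, object] = {
            "n": int(len(sub)),
            "v95_success_rate_pct": {
                "RO": success_rate(sub["ro_v95_pass"]),
                "DIR": success_rate(sub["dir_v95_pass"]),
            },
        }
        for m in ("d95_rel_pct", "d50_rel_pct", "dmax_rel_pct"):
            entry[m] = summarize(dict(zip(sid, sub[m])), group=f"{group}:{m}")
        dsub = dd_df[dd_df["group"] == group]
        did = dsub["case_id"] + "/" + dsub["label"]
        for t in config.dd_taus:
            col = f"dd_{100 * t:g}pct"
            entry[col] = summarize(dict(zip(did, dsub[col])), group=f"{group}:{col}")
        summaries[group] = entry
    return {"dvh_rows": dvh_df, "dd_rows": dd_df, "summaries": summaries}


def run_reproducibility(
    bundles: Sequence[CaseBundle],
    config: RunConfig,
    study_dd_rows: Optional[pd.DataFrame] = None,
) -> Dict:
    """Optimizer-variability DD analysis over replicate-plan pairs.

    Each case's replicate plans are compared pairwise (5 replicates ->
    10 combinations); pass-rate distributions are then compared against the
    study (DIR vs. RO) distributions with Mann–Whitney tests per group and
    threshold.
    """
    rows = []
    skipped: List[str] = []
    for bundle in bundles:
        rep_ids = sorted(k for k in bundle.doses if k.startswith("RO_rep"))
        if len(rep_ids) < 2:
            skipped.append(bundle.case_id)
            warnings.warn(
                f"{bundle.case_id}: fewer than 2 dose replicates; skipped"
            )
            continue
        design = build_reproducibility_pairs(rep_ids, case_id=bundle.case_id)
        for group, structs in _dose_groups(bundle).items():
            for s in structs:
                if s.is_empty:
                    continue
                for pa, pb in design.pairs:
                    dd = dd_pass_rates(
                        bundle.doses[pa], bundle.doses[pb], s,
                        taus=config.dd_taus,
                        low_dose_guard_gy=config.low_dose_guard_gy,
                        signed=config.signed_dd,
                    )
                    rows.append(
                        {
                            "case_id": bundle.case_id,
                            "label": s.label,
                            "group": group,
                            "pair": f"{pa}|{pb}",
                            **{
                                f"dd_{100 * t:g}pct": dd.pass_rates_pct[t]
                                for t in config.dd_taus
                            },
                        }
                    )
    df = pd.DataFrame(rows)
    tests: Dict[str, object] = {}
    if study_dd_rows is not None and not study_dd_rows.empty and not df.empty:
        study: Dict[Tuple[str, float], Sequence[float]] = {}
        optim: Dict[Tuple[str, float], Sequence[float]] = {}
        for group in ("GTV+CTV", "PTV"):
            for t in config.dd_taus:
                col = f"dd_{100 * t:g}pct"
                s_vals = study_dd_rows.loc[study_dd_rows["group"] == group, col]
                o_vals = df.loc[df["group"] == group, col]
                if len(s_vals) and len(o_vals):
                    study[(group, t)] = s_vals.to_numpy()
                    optim[(group, t)] = o_vals.to_numpy()
        tests = {
            f"{g}|dd_{100 * t:g}pct": res
            for (g, t), res in compare_variability(study, optim).items()
        }
    return {"rows": df, "study_vs_optimizer": tests, "skipped_cases": skipped}


def run_all(bundles: Sequence[CaseBundle], config: RunConfig) -> StudyReport:
    """Full study replication over a cohort of case bundles."""
    geo = run_geometric(bundles, config)
    dose = run_dosimetric(bundles, config)
    repro = run_reproducibility(bundles, config, study_dd_rows=dose["dd_rows"])
    return StudyReport(
        geometric_rows=geo["rows"],
        geometric_summaries=geo["summaries"],
        tumor_vs_node=geo["tumor_vs_node"],
        correlations=geo["correlations"],
        dvh_rows=dose["dvh_rows"],
        dd_rows=dose["dd_rows"],
        dose_summaries=dose["summaries"],
        repro_rows=repro["rows"],
        study_vs_optimizer=repro["study_vs_optimizer"],
        manifest=config.manifest(),
        warnings_=geo["warnings"]
        + [f"skipped (no replicates): {c}" for c in repro["skipped_cases"]]
        + [
            "note: structures from one patient are treated as independent "
            "observations in all tests (no clustering adjustment)"
        ],
    )


def _jsonable(obj):
    if isinstance(obj, MetricDistribution):
        return {
            "group": obj.group,
            "median": obj.median,
            "q1": obj.q1,
            "q3": obj.q3,
            "n": obj.n,
            "n_excluded": obj.n_excluded,
            "outliers_beyond_1p5_iqr": obj.outliers,
        }
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_report(report: StudyReport, out_dir, fmt: str = "csv") -> None:
    """Emit machine-readable tables + a JSON summary + the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "geometric": report.geometric_rows,
        "dvh": report.dvh_rows,
        "dd": report.dd_rows,
        "reproducibility": report.repro_rows,
    }
    for name, df in tables.items():
        if fmt == "csv":
            df.to_csv(out / f"{name}.csv", index=False)
        elif fmt == "json":
            df.to_json(out / f"{name}.json", orient="records", indent=1)
        else:
            raise ValidationError(f"unknown report format {fmt!r}")
    summary = {
        "geometric_summaries": _jsonable(report.geometric_summaries),
        "tumor_vs_node": _jsonable(report.tumor_vs_node),
        "correlations": _jsonable(report.correlations),
        "dose_summaries": _jsonable(report.dose_summaries),
        "study_vs_optimizer": _jsonable(report.study_vs_optimizer),
        "warnings": report.warnings_,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(_jsonable(report.manifest), indent=1, sort_keys=True)
    )
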