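"""Cohort-level aggregation and statistical comparisons.

Per-structure metrics are summarized as medians and quartiles
(linear-interpolation percentiles) with explicit not-evaluable exclusion
counts.  Group comparisons use the two-sided Mann–Whitney U test — exact by
full enumeration of rank splits when both samples have n ≤ 8 (the
enumeration handles ties, which matters for identical small samples), and
the normal approximation with tie and continuity corrections otherwise.
Metric-vs-volume-change relationships use Pearson correlation with a
t-transform p-value and a Fisher-z 95% confidence interval.

Structures from one patient are treated as independent observations, as is
common in small DIR-commissioning cohorts; reports should flag this
clustering rather than model it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import NotEvaluableError, ValidationError

__all__ = [
    "MetricDistribution",
    "TestResult",
    "CorrelationResult",
    "ReproducibilityDesign",
    "summarize",
    "mann_whitney_u",
    "pearson",
    "build_reproducibility_pairs",
    "compare_variability",
    "ALPHA",
]

#: Significance level used throughout.
ALPHA = 0.05

#: Largest per-sample size for which the exact Mann–Whitney enumeration runs.
EXACT_MWU_MAX_N = 8


@dataclass
class MetricDistribution:
    """Median/quartile summary of one metric over one group of structures."""

    group: str
    values: Dict[str, float]  # structure id -> value (evaluable only)
    median: float
    q1: float
    q3: float
    n: int
    n_excluded: int
    outliers: List[str] = field(default_factory=list)  # beyond 1.5*IQR, annotated


def summarize(
    values: Dict[str, float] | Sequence[Tuple[str, float]], group: str = ""
) -> MetricDistribution:
    """Summarize ``{structure id: value}``; NaN values count as excluded.

    No automatic outlier removal is done — values beyond 1.5×IQR of the
    quartiles are only *annotated* (real cohorts keep and discuss their
    outliers, e.g. a huge HD95 from new nodal disease).
    """
    items = dict(values)
    evaluable = {k: float(v) for k, v in items.items() if not math.isnan(float(v))}
    n_excluded = len(items) - len(evaluable)
    if not evaluable:
        raise NotEvaluableError(f"group {group!r}: no evaluable values")
    arr = np.array(list(evaluable.values()))
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = sorted(k for k, v in evaluable.items() if v < lo or v > hi)
    return MetricDistribution(
        group=group,
        values=evaluable,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        n=len(evaluable),
        n_excluded=n_excluded,
        outliers=outliers,
    )


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    two_sided: bool = True
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: #(x_i > y_j) + 0.5 * #(ties), via midranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = EXACT_MWU_MAX_N,
    name: str = "mann-whitney",
) -> TestResult:
    """Two-sided Mann–Whitney U test.

    When both sample sizes are ≤ ``exact_max_n`` the null distribution of U
    is enumerated over all C(n+m, n) assignments of the pooled values (tie
    safe); the two-sided p-value is the folded tail
    ``P(max(U, nm-U) >= max(u, nm-u))`` over that null distribution.
    Larger samples use the normal approximation with tie and continuity
    corrections.  The statistic reported is U for ``x``:
    ``#(x_i > y_j) + 0.5 * #(ties)``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("Mann–Whitney requires both samples nonempty")
    n, m = x.size, y.size
    u = _u_statistic(x, y)
    if n <= exact_max_n and m <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = np.arange(n + m)
        u_hi = max(u, n * m - u)
        count = total = 0
        for comb in combinations(idx, n):
            comb = np.array(comb)
            mask = np.zeros(n + m, dtype=bool)
            mask[comb] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if max(u_perm, n * m - u_perm) >= u_hi - 1e-12:
                count += 1
        p = min(1.0, count / total)  # both tails already folded into u_hi
        method = "exact enumeration"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        method = "normal approximation (tie + continuity corrected)"
    return TestResult(name=name, statistic=u, p_value=p, two_sided=True,
                      method=method)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-9:
            raise ValidationError(f"|r| must be <= 1, got {self.r}")
        if not (self.ci_low - 1e-9 <= self.r <= self.ci_high + 1e-9):
            raise ValidationError("r must lie inside its confidence interval")


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with t-transform p and Fisher-z 95% CI."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("Pearson correlation requires paired samples, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise NotEvaluableError("Pearson correlation undefined for zero variance")
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    n = x.size
    if n > 3 and abs(r) < 1:
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
    else:
        lo, hi = -1.0, 1.0  # Fisher z degenerate at n = 3 or |r| = 1
    return CorrelationResult(r=r, p_value=p, ci_low=lo, ci_high=hi, n=n)


@dataclass
class ReproducibilityDesign:
    """All unordered pairwise comparisons among one case's replicate plans."""

    case_id: str
    replicate_ids: List[str]
    pairs: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        n = len(self.replicate_ids)
        if len(self.pairs) != n * (n - 1) // 2:
            raise ValidationError("pair count must equal n(n-1)/2")
        if any(a == b for a, b in self.pairs):
            raise ValidationError("self-pairs are not allowed")
        if len(set(map(frozenset, self.pairs))) != len(self.pairs):
            raise ValidationError("duplicate pairs are not allowed")


def build_reproducibility_pairs(
    replicate_ids: Sequence[str], case_id: str = ""
) -> ReproducibilityDesign:
    """All n(n-1)/2 unordered pairs of replicate plans (5 replicates -> 10)."""
    ids = list(replicate_ids)
    if len(ids) < 2:
        raise ValidationError("reproducibility design needs >= 2 replicates")
    if len(set(ids)) != len(ids):
        raise ValidationError("replicate ids must be distinct")
    return ReproducibilityDesign(
        case_id=case_id, replicate_ids=ids, pairs=list(combinations(ids, 2))
    )


def compare_variability(
    study_dd: Dict[Tuple[str, float], Sequence[float]],
    optimizer_dd: Dict[Tuple[str, float], Sequence[float]],
) -> Dict[Tuple[str, float], TestResult]:
    """Mann–Whitney study-vs-optimizer DD comparison per (group, tau) key."""
    out: Dict[Tuple[str, float], TestResult] = {}
    for key in sorted(set(study_dd) & set(optimizer_dd)):
        group, tau = key
        out[key] = mann_whitney_u(
            study_dd[key],
            optimizer_dd[key],
            name=f"DD study-vs-optimizer {group} tau={tau:g}",
        )
    return out
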