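"""Cohort aggregation, two-model comparison, and concordance analysis.

Per-patient metrics are aggregated unweighted across patients (mean ± SD
and median with first–third quartiles). Two models evaluated on the same
cohort are compared metric-by-metric with two-sided Mann–Whitney U tests on
the per-patient values, and the difference of cohort means is reported in
percentage points (model B minus model A). The concordance analysis
classifies every GT lesion instance by which model(s) detected it, and
summarizes model B's net additional detections per patient.

No multiple-testing correction is applied: one raw p-value is reported per
metric, and significance is flagged at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instances import InstanceMap, MatchResult
from .metrics import METRIC_FIELDS, PatientMetrics

__all__ = [
    "CohortSummary",
    "ComparisonReport",
    "ConcordanceResult",
    "MannWhitneyResult",
    "aggregate",
    "mann_whitney_u",
    "compare_models",
    "gap_closure",
    "concordance",
    "net_additional_per_patient",
]

ALPHA = 0.05

#: Quartiles use linear interpolation between order statistics ("type 7").
_QUANTILE_METHOD = "linear"


@dataclass
class CohortSummary:
    """Per-metric cohort statistics (values on the [0, 1] scale)."""

    table: pd.DataFrame  # index: metric; columns: mean, sd, median, q1, q3, n_patients
    flags: frozenset[str] = field(default_factory=frozenset)

    def __getitem__(self, metric: str) -> pd.Series:
        return self.table.loc[metric]


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # 'exact', 'asymptotic' or 'degenerate'


@dataclass
class ComparisonReport:
    """B-minus-A deltas (percentage points) and Mann–Whitney p per metric."""

    model_a: str
    model_b: str
    metrics: dict[str, dict]  # per metric: delta_points, u_statistic, p_value, significant
    n_patients: int

    def to_dict(self) -> dict:
        return {
            "model_a": self.model_a,
            "model_b": self.model_b,
            "n_patients": self.n_patients,
            "alpha": ALPHA,
            "metrics": self.metrics,
        }


@dataclass
class ConcordanceResult:
    """Status of every GT instance under two models' matchings."""

    records: pd.DataFrame  # patient_id, gt_id, volume_cm3, status
    counts: dict[str, int]  # both, A_only, B_only, neither
    net_additional_per_patient: float
    n_patients: int


def aggregate(metrics: list[PatientMetrics]) -> CohortSummary:
    """Unweighted cohort summary of the six per-patient metrics.

    SD uses the n-1 denominator; a single-patient cohort gets sd = 0 and is
    flagged ``n=1``. Quartiles are linearly interpolated.
    """
    if not metrics:
        raise ValueError("cannot aggregate an empty cohort")
    rows = {}
    for m in METRIC_FIELDS:
        vals = np.array([getattr(pm, m) for pm in metrics], dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method=_QUANTILE_METHOD)
        rows[m] = {
            "mean": float(vals.mean()),
            "sd": sd,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "n_patients": vals.size,
        }
    flags = frozenset({"n=1"}) if len(metrics) == 1 else frozenset()
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(METRIC_FIELDS)]
    return CohortSummary(table, flags)


def _enumerate_u(pooled: np.ndarray, n_a: int) -> np.ndarray:
    """U statistic of the first group for every assignment of the pooled
    sample into groups of sizes (n_a, n - n_a). Midrank convention:
    each (a, b) pair contributes 1 if a > b and 1/2 if a == b."""
    from itertools import combinations

    n = pooled.size
    out = []
    for idx in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        ga, gb = pooled[mask], pooled[~mask]
        gt = (ga[:, None] > gb[None, :]).sum()
        eq = (ga[:, None] == gb[None, :]).sum()
        out.append(gt + 0.5 * eq)
    return np.array(out)


def mann_whitney_u(sample_a, sample_b) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test with midrank ties.

    For small samples (both n <= 8) the null distribution is computed
    exactly: via the classical exact distribution when there are no ties,
    and by exhaustive enumeration of all group assignments of the pooled
    (tied) sample otherwise, with the two-sided p-value defined as the
    null probability of a U at least as far from its mean as observed.
    Larger samples use the normal approximation with tie and continuity
    corrections. Two identical constant samples carry no rank information:
    U = n_a * n_b / 2 and p = 1 ('degenerate').
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(a.size * b.size / 2.0, 1.0, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size <= 8 and b.size <= 8
    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MannWhitneyResult(float(res.statistic), min(float(res.pvalue), 1.0), "exact")
    if small:
        u_obs = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="asymptotic").statistic)
        u_all = _enumerate_u(pooled, a.size)
        mu = a.size * b.size / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-12))
        return MannWhitneyResult(u_obs, p, "exact")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MannWhitneyResult(float(res.statistic), min(float(res.pvalue), 1.0), "asymptotic")


def compare_models(
    metrics_a: list[PatientMetrics],
    metrics_b: list[PatientMetrics],
    model_a: str = "A",
    model_b: str = "B",
) -> ComparisonReport:
    """Metric-wise comparison of two models on the same cohort.

    Deltas are differences of cohort means on the 0–100 scale (B minus A);
    p-values come from two-sided Mann–Whitney U tests on the per-patient
    values of each metric.
    """
    ids_a = sorted(pm.patient_id for pm in metrics_a)
    ids_b = sorted(pm.patient_id for pm in metrics_b)
    if ids_a != ids_b:
        only_a = sorted(set(ids_a) - set(ids_b))
        only_b = sorted(set(ids_b) - set(ids_a))
        raise ValueError(
            f"patient sets differ between models: only in A {only_a[:5]}, only in B {only_b[:5]}"
        )
    out: dict[str, dict] = {}
    for m in METRIC_FIELDS:
        va = np.array([getattr(pm, m) for pm in metrics_a], dtype=float)
        vb = np.array([getattr(pm, m) for pm in metrics_b], dtype=float)
        test = mann_whitney_u(va, vb)
        out[m] = {
            "delta_points": float((vb.mean() - va.mean()) * 100.0),
            "u_statistic": test.u_statistic,
            "p_value": test.p_value,
            "significant": bool(test.p_value < ALPHA),
        }
    return ComparisonReport(model_a, model_b, out, len(metrics_a))


def gap_closure(mean_a: float, mean_b: float, mean_c: float) -> float:
    """Fraction of the A-to-C performance gap closed by B: (B - A)/(C - A)."""
    if mean_c == mean_a:
        raise ValueError("gap closure undefined: reference models A and C have equal means")
    return (mean_b - mean_a) / (mean_c - mean_a)


def net_additional_per_patient(n_b_only: int, n_a_only: int, n_patients: int) -> float:
    """Model B's net additional detected instances per patient.

    (#instances found only by B - #instances found only by A) / #patients.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if min(n_b_only, n_a_only) < 0:
        raise ValueError("counts must be nonnegative")
    return (n_b_only - n_a_only) / n_patients


def concordance(
    matches_a: dict[str, MatchResult],
    matches_b: dict[str, MatchResult],
    gt_maps: dict[str, InstanceMap],
) -> ConcordanceResult:
    """Classify every GT instance as found by both models, one, or neither.

    Both models must have been matched against the same GT instance maps.
    Records carry lesion volumes so they can be exported ordered by volume.
    """
    if set(matches_a) != set(matches_b) or set(matches_a) != set(gt_maps):
        raise ValueError("patient ids of the two matchings and the GT maps must coincide")
    rows = []
    counts = {"both": 0, "A_only": 0, "B_only": 0, "neither": 0}
    for pid in sorted(gt_maps):
        gt = gt_maps[pid]
        ma, mb = matches_a[pid], matches_b[pid]
        for res, name in ((ma, "A"), (mb, "B")):
            seen = res.matched_gt | res.unmatched_gt
            if seen != gt.ids:
                raise ValueError(
                    f"patient {pid!r}: model {name} matching refers to GT instances "
                    f"{sorted(seen)} but the GT map has {sorted(gt.ids)}"
                )
        in_a, in_b = ma.matched_gt, mb.matched_gt
        vols = gt.volumes()
        for g in sorted(gt.ids):
            if g in in_a and g in in_b:
                status = "both"
            elif g in in_a:
                status = "A_only"
            elif g in in_b:
                status = "B_only"
            else:
                status = "neither"
            counts[status] += 1
            rows.append((pid, g, vols[g], status))
    records = pd.DataFrame(rows, columns=["patient_id", "gt_id", "volume_cm3", "status"])
    net = net_additional_per_patient(counts["B_only"], counts["A_only"], len(gt_maps))
    return ConcordanceResult(records, counts, net, len(gt_maps))
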