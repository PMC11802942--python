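"""End-to-end evaluation pipeline: manifest -> per-patient metrics ->
cohort summaries -> model comparison and concordance exports.

All CSV/JSON outputs use fixed float formatting, so reruns on identical
inputs are byte-identical. Summary tables are rendered on the 0-100
percentage scale with one decimal; per-patient tables keep full precision
on the [0, 1] scale.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import ComparisonReport, aggregate, compare_models, concordance
from .instances import (
    DEFAULT_DSC_THRESHOLD,
    InstanceMap,
    MatchResult,
    extract_instances,
    match_instances,
    pairwise_dsc,
)
from .manifest import CohortManifest
from .metrics import METRIC_FIELDS, PatientMetrics, evaluate_patient
from .volume import read_label_volume

__all__ = ["evaluate_cohort", "run_pipeline"]


def evaluate_cohort(
    manifest: CohortManifest,
    model: str,
    gt_role: str = "haq",
    connectivity: int = 26,
    threshold: float = DEFAULT_DSC_THRESHOLD,
    skip_errors: bool = False,
) -> tuple[list[PatientMetrics], dict[str, MatchResult], dict[str, InstanceMap]]:
    """Evaluate one model against one GT role for every manifest patient.

    Returns the per-patient metrics plus the match results and GT instance
    maps needed for a later concordance analysis.
    """
    metrics: list[PatientMetrics] = []
    matches: dict[str, MatchResult] = {}
    gt_maps: dict[str, InstanceMap] = {}
    for pid in manifest.patient_ids:
        try:
            gt_mask = read_label_volume(manifest.path(pid, gt_role))
            pred_mask = read_label_volume(manifest.path(pid, model))
            gt = extract_instances(gt_mask, connectivity)
            pred = extract_instances(pred_mask, connectivity)
            overlaps = pairwise_dsc(gt, pred)
            match = match_instances(gt, pred, threshold, overlaps=overlaps)
            pm = evaluate_patient(
                gt_mask, pred_mask, connectivity, threshold, patient_id=pid
            )
        except Exception as exc:
            if skip_errors:
                continue
            raise RuntimeError(f"evaluation failed for patient {pid!r}: {exc}") from exc
        metrics.append(pm)
        matches[pid] = match
        gt_maps[pid] = gt
    if not metrics:
        raise RuntimeError("no patients could be evaluated")
    return metrics, matches, gt_maps


def _write_per_patient_csv(per_model: dict[str, list[PatientMetrics]], path: Path) -> None:
    rows = []
    for model, pms in per_model.items():
        for pm in pms:
            d = pm.as_dict()
            d["model"] = model
            rows.append(d)
    df = pd.DataFrame(rows)
    cols = ["patient_id", "model", "tp", "fp", "fn", *METRIC_FIELDS, "degenerate_flags"]
    df = df[cols]
    df[list(METRIC_FIELDS)] = df[list(METRIC_FIELDS)].map(lambda x: f"{x:.6f}")
    df.to_csv(path, index=False)


def _write_summary_csv(summaries: dict[str, pd.DataFrame], path: Path) -> None:
    rows = []
    for model, table in summaries.items():
        for metric, r in table.iterrows():
            rows.append(
                {
                    "model": model,
                    "metric": metric,
                    "mean_pct": f"{r['mean'] * 100:.1f}",
                    "sd_pct": f"{r['sd'] * 100:.1f}",
                    "median_pct": f"{r['median'] * 100:.1f}",
                    "q1_pct": f"{r['q1'] * 100:.1f}",
                    "q3_pct": f"{r['q3'] * 100:.1f}",
                    "n_patients": int(r["n_patients"]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def run_pipeline(
    manifest: CohortManifest,
    model_names: list[str],
    out_dir: str | Path,
    gt_role: str = "haq",
    connectivity: int = 26,
    threshold: float = DEFAULT_DSC_THRESHOLD,
    skip_errors: bool = False,
) -> dict:
    """Run evaluation (and, with two models, comparison + concordance).

    Writes ``per_patient_metrics.csv``, ``cohort_summary.csv``, and — when
    two models are given — ``comparison.json`` and ``concordance.csv``
    (GT instances sorted by lesion volume), plus ``run_log.json``.
    """
    if not 1 <= len(model_names) <= 2:
        raise ValueError("run_pipeline takes one or two model names")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    per_model: dict[str, list[PatientMetrics]] = {}
    matches: dict[str, dict[str, MatchResult]] = {}
    gt_maps: dict[str, InstanceMap] = {}
    for model in model_names:
        pms, mt, gm = evaluate_cohort(
            manifest, model, gt_role, connectivity, threshold, skip_errors
        )
        per_model[model] = pms
        matches[model] = mt
        gt_maps = gm

    _write_per_patient_csv(per_model, out_dir / "per_patient_metrics.csv")
    summaries = {m: aggregate(pms).table for m, pms in per_model.items()}
    _write_summary_csv(summaries, out_dir / "cohort_summary.csv")

    result: dict = {"summaries": summaries}
    if len(model_names) == 2:
        a, b = model_names
        report: ComparisonReport = compare_models(per_model[a], per_model[b], a, b)
        (out_dir / "comparison.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        conc = concordance(matches[a], matches[b], gt_maps)
        recs = conc.records.sort_values(
            ["volume_cm3", "patient_id", "gt_id"], kind="mergesort"
        ).copy()
        recs["volume_cm3"] = recs["volume_cm3"].map(lambda x: f"{x:.6f}")
        recs.to_csv(out_dir / "concordance.csv", index=False)
        result["comparison"] = report
        result["concordance"] = conc

    log = {
        "models": model_names,
        "gt_role": gt_role,
        "connectivity": connectivity,
        "dsc_threshold": threshold,
        "n_patients": len(manifest.patient_ids),
        "instance_counts": {
            pid: gt_maps[pid].n_instances for pid in sorted(gt_maps)
        },
        "versions": {
            "lesionwise": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    result["log"] = log
    return result
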