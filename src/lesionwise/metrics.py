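"""Per-patient detection and lesion-wise segmentation metrics.

Two families of metrics are computed per patient and later aggregated
across the cohort (patients are the unit of aggregation, so a patient with
one lesion weighs as much as a patient with ten):

* *detection* metrics — instance-level PPV, sensitivity and F1 from the
  tp/fp/fn counts of the DSC matching;
* *lesion-wise (LW) voxel* metrics — voxel DSC and sensitivity averaged
  over GT instances, and voxel PPV averaged over predicted instances.
  Unmatched instances contribute 0, so detection failures also depress the
  segmentation scores.

Degenerate denominators follow the "no false claims" convention: with zero
predicted instances PPV := 1 (flagged ``no_predictions``), with zero GT
instances sensitivity := 1 (flagged ``no_gt``). Flags are kept on the
record so downstream users can re-aggregate under a different convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instances import (
    DEFAULT_DSC_THRESHOLD,
    InstanceMap,
    MatchResult,
    classify_detections,
    extract_instances,
    match_instances,
    pairwise_dsc,
)
from .volume import LabelVolume

__all__ = [
    "PatientMetrics",
    "METRIC_FIELDS",
    "detection_metrics",
    "lesionwise_voxel_metrics",
    "evaluate_patient",
]

#: The six per-patient metric fields, in reporting order.
METRIC_FIELDS = ("inst_f1", "inst_ppv", "inst_sn", "lw_dsc", "lw_ppv", "lw_sn")


@dataclass
class PatientMetrics:
    patient_id: str
    tp: int
    fp: int
    fn: int
    inst_ppv: float
    inst_sn: float
    inst_f1: float
    lw_dsc: float
    lw_ppv: float
    lw_sn: float
    degenerate_flags: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        d = {
            "patient_id": self.patient_id,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }
        d.update({m: getattr(self, m) for m in METRIC_FIELDS})
        d["degenerate_flags"] = ";".join(sorted(self.degenerate_flags))
        return d


def detection_metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Instance-level (PPV, sensitivity, F1) from detection counts.

    ppv = tp/(tp+fp), sn = tp/(tp+fn), f1 = 2 tp/(2 tp + fp + fn); an empty
    denominator yields 1 (nothing was claimed / nothing was there to find).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    ppv = tp / (tp + fp) if tp + fp > 0 else 1.0
    sn = tp / (tp + fn) if tp + fn > 0 else 1.0
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom > 0 else 1.0
    return ppv, sn, f1


def _pair_intersections(
    gt: InstanceMap, pred: InstanceMap, match: MatchResult
) -> dict[tuple[int, int], int]:
    inter: dict[tuple[int, int], int] = {}
    for g, p, _ in match.pairs:
        inter[(g, p)] = int(np.count_nonzero((gt.labels == g) & (pred.labels == p)))
    return inter


def lesionwise_voxel_metrics(
    gt: InstanceMap, pred: InstanceMap, match: MatchResult
) -> tuple[float, float, float]:
    """Per-patient lesion-wise (lw_dsc, lw_ppv, lw_sn).

    For each GT instance: voxel DSC and voxel sensitivity against its
    matched prediction (0 if unmatched); for each predicted instance: voxel
    PPV against its matched GT instance (0 if unmatched). lw_dsc/lw_sn are
    means over GT instances, lw_ppv the mean over predicted instances. Each
    pair's voxel overlap is computed over that pair's voxels only.

    With no GT instances lw_dsc = lw_sn = 1; with no predicted instances
    lw_ppv = 1 (degeneracy is flagged by the caller).
    """
    inter = _pair_intersections(gt, pred, match)
    gsize = gt.voxel_counts()
    psize = pred.voxel_counts()
    g_pair = match.pair_for_gt()
    p_pair = match.pair_for_pred()

    dscs, sns = [], []
    for g in sorted(gt.ids):
        if g in g_pair:
            p, _ = g_pair[g]
            i = inter[(g, p)]
            dscs.append(2.0 * i / (gsize[g] + psize[p]))
            sns.append(i / gsize[g])
        else:
            dscs.append(0.0)
            sns.append(0.0)
    ppvs = []
    for p in sorted(pred.ids):
        if p in p_pair:
            g, _ = p_pair[p]
            ppvs.append(inter[(g, p)] / psize[p])
        else:
            ppvs.append(0.0)

    lw_dsc = float(np.mean(dscs)) if dscs else 1.0
    lw_sn = float(np.mean(sns)) if sns else 1.0
    lw_ppv = float(np.mean(ppvs)) if ppvs else 1.0
    return lw_dsc, lw_ppv, lw_sn


def evaluate_patient(
    gt_mask: LabelVolume,
    pred_mask: LabelVolume,
    connectivity: int = 26,
    threshold: float = DEFAULT_DSC_THRESHOLD,
    patient_id: str = "",
    matching: str = "greedy",
) -> PatientMetrics:
    """Full per-patient evaluation of one prediction against one GT mask.

    Composes instance extraction, pairwise DSC, one-to-one matching,
    detection counting, and both metric families into a single record.
    """
    try:
        if gt_mask.shape != pred_mask.shape:
            raise ValueError(
                f"grid mismatch: GT {gt_mask.shape} vs prediction {pred_mask.shape}"
            )
        gt = extract_instances(gt_mask, connectivity)
        pred = extract_instances(pred_mask, connectivity)
        overlaps = pairwise_dsc(gt, pred)
        match = match_instances(gt, pred, threshold, method=matching, overlaps=overlaps)
        counts = classify_detections(match)
        ppv, sn, f1 = detection_metrics(**counts)
        lw_dsc, lw_ppv, lw_sn = lesionwise_voxel_metrics(gt, pred, match)
    except Exception as exc:
        raise type(exc)(f"patient {patient_id!r}: {exc}") from exc

    flags = set()
    if pred.n_instances == 0:
        flags.add("no_predictions")
    if gt.n_instances == 0:
        flags.add("no_gt")
    return PatientMetrics(
        patient_id=patient_id,
        **counts,
        inst_ppv=ppv,
        inst_sn=sn,
        inst_f1=f1,
        lw_dsc=lw_dsc,
        lw_ppv=lw_ppv,
        lw_sn=lw_sn,
        degenerate_flags=frozenset(flags),
    )
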