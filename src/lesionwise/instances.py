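"""Instance extraction and Dice-based detection matching.

Binary masks are decomposed into *instances* — maximal connected components
under a chosen 3D connectivity (6, 18 or 26 neighbours). Ground-truth and
predicted instances are paired one-to-one by Dice similarity coefficient
(DSC); a ground-truth lesion counts as *detected* when the DSC of its pair
strictly exceeds a threshold (default 0.1). The threshold is deliberately
lenient: it asks whether the lesion was found at all, not how well it was
delineated.

DSC is computed on voxel counts; spacing enters only via the reported
physical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .volume import LabelVolume

__all__ = [
    "InstanceRecord",
    "InstanceMap",
    "MatchResult",
    "extract_instances",
    "pairwise_dsc",
    "match_instances",
    "classify_detections",
]

#: DSC above which a GT/prediction instance pair counts as a detection.
DEFAULT_DSC_THRESHOLD = 0.1

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class InstanceRecord:
    id: int
    voxel_count: int
    volume_cm3: float


@dataclass
class InstanceMap:
    """Integer-labelled volume (0 = background, 1..K = instances)."""

    labels: np.ndarray
    records: list[InstanceRecord]
    spacing_mm: tuple[float, float, float]

    @property
    def n_instances(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> set[int]:
        return {r.id for r in self.records}

    def voxel_counts(self) -> dict[int, int]:
        return {r.id: r.voxel_count for r in self.records}

    def volumes(self) -> dict[int, float]:
        return {r.id: r.volume_cm3 for r in self.records}


@dataclass
class MatchResult:
    """One-to-one GT<->prediction pairing above a DSC threshold.

    ``pairs`` holds (gt_id, pred_id, dsc) triples with dsc strictly above
    ``threshold``; every instance id appears in at most one pair, and the
    pairs plus the two unmatched sets partition all instances.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_gt: set[int]
    unmatched_pred: set[int]
    threshold: float = DEFAULT_DSC_THRESHOLD

    @property
    def matched_gt(self) -> set[int]:
        return {g for g, _, _ in self.pairs}

    @property
    def matched_pred(self) -> set[int]:
        return {p for _, p, _ in self.pairs}

    def pair_for_gt(self) -> dict[int, tuple[int, float]]:
        return {g: (p, d) for g, p, d in self.pairs}

    def pair_for_pred(self) -> dict[int, tuple[int, float]]:
        return {p: (g, d) for g, p, d in self.pairs}


def extract_instances(mask: LabelVolume, connectivity: int = 26) -> InstanceMap:
    """Label maximal connected components of a binary mask.

    Parameters
    ----------
    mask : LabelVolume
    connectivity : {6, 18, 26}
        3D neighbourhood: faces only, faces+edges, or faces+edges+corners.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}, got {connectivity}")
    labels, n = ndimage.label(mask.voxels, structure=_STRUCTS[connectivity])
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    vv_cm3 = mask.voxel_volume_cm3
    records = [
        InstanceRecord(i, int(counts[i]), float(counts[i]) * vv_cm3)
        for i in range(1, n + 1)
    ]
    return InstanceMap(labels.astype(np.int32), records, mask.spacing_mm)


def pairwise_dsc(gt: InstanceMap, pred: InstanceMap) -> list[tuple[int, int, float]]:
    """DSC for every overlapping (gt instance, prediction instance) pair.

    Returns (gt_id, pred_id, dsc) triples for pairs with nonzero voxel
    intersection, sorted by (gt_id, pred_id). DSC(A, B) = 2|A∩B|/(|A|+|B|).
    """
    if gt.labels.shape != pred.labels.shape:
        raise ValueError(
            f"grid shape mismatch: GT {gt.labels.shape} vs prediction {pred.labels.shape}"
        )
    both = (gt.labels > 0) & (pred.labels > 0)
    if not both.any():
        return []
    g = gt.labels[both].astype(np.int64)
    p = pred.labels[both].astype(np.int64)
    keys, counts = np.unique(g * (pred.labels.max() + 1) + p, return_counts=True)
    gsizes = gt.voxel_counts()
    psizes = pred.voxel_counts()
    base = int(pred.labels.max()) + 1
    out = []
    for key, inter in zip(keys.tolist(), counts.tolist()):
        gid, pid = divmod(key, base)
        out.append((gid, pid, 2.0 * inter / (gsizes[gid] + psizes[pid])))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def match_instances(
    gt: InstanceMap,
    pred: InstanceMap,
    threshold: float = DEFAULT_DSC_THRESHOLD,
    method: str = "greedy",
    overlaps: list[tuple[int, int, float]] | None = None,
) -> MatchResult:
    """One-to-one matching of GT and prediction instances by DSC.

    ``method='greedy'`` (default): candidate pairs sorted by descending DSC
    (ties broken by larger GT volume, then smaller gt_id, then smaller
    pred_id); a pair is accepted iff both ids are still free and its DSC
    strictly exceeds ``threshold``. ``method='maxweight'`` instead maximizes
    total DSC over one-to-one assignments (Hungarian algorithm) and keeps
    assigned pairs above threshold.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if overlaps is None:
        overlaps = pairwise_dsc(gt, pred)
    candidates = [(g, p, d) for g, p, d in overlaps if d > threshold]

    pairs: list[tuple[int, int, float]] = []
    if method == "greedy":
        gvol = gt.volumes()
        candidates.sort(key=lambda t: (-t[2], -gvol.get(t[0], 0.0), t[0], t[1]))
        used_g: set[int] = set()
        used_p: set[int] = set()
        for g, p, d in candidates:
            if g not in used_g and p not in used_p:
                pairs.append((g, p, d))
                used_g.add(g)
                used_p.add(p)
    elif method == "maxweight":
        if candidates:
            gids = sorted({g for g, _, _ in candidates})
            pids = sorted({p for _, p, _ in candidates})
            gi = {g: i for i, g in enumerate(gids)}
            pi = {p: i for i, p in enumerate(pids)}
            w = np.zeros((len(gids), len(pids)))
            for g, p, d in candidates:
                w[gi[g], pi[p]] = d
            rows, cols = linear_sum_assignment(w, maximize=True)
            for r, c in zip(rows, cols):
                if w[r, c] > threshold:
                    pairs.append((gids[r], pids[c], float(w[r, c])))
            pairs.sort(key=lambda t: -t[2])
    else:
        raise ValueError(f"unknown matching method {method!r}")

    matched_g = {g for g, _, _ in pairs}
    matched_p = {p for _, p, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_gt=gt.ids - matched_g,
        unmatched_pred=pred.ids - matched_p,
        threshold=threshold,
    )


def classify_detections(match: MatchResult) -> dict[str, int]:
    """Detection counts: tp = matched pairs, fn = unmatched GT, fp = unmatched predictions."""
    return {
        "tp": len(match.pairs),
        "fp": len(match.unmatched_pred),
        "fn": len(match.unmatched_gt),
    }
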