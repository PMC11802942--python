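"""Brute-force reference implementations used only by the tests.

Everything here is deliberately naive — explicit neighbour offsets,
flood-fill with a python queue, exhaustive enumeration of assignments —
and independent of the package's scipy-based implementations.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations, permutations

import numpy as np


def neighbor_offsets(connectivity: int):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components as sets of voxel index tuples."""
    offs = neighbor_offsets(connectivity)
    todo = {tuple(ix) for ix in np.argwhere(mask)}
    comps = []
    while todo:
        seed = next(iter(todo))
        todo.discard(seed)
        comp = {seed}
        queue = deque([seed])
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offs:
                nb = (x + dx, y + dy, z + dz)
                if nb in todo:
                    todo.discard(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def dice(a: set, b: set) -> float:
    return 2.0 * len(a & b) / (len(a) + len(b))


def brute_overlap_table(gt_comps: dict[int, set], pred_comps: dict[int, set]):
    out = []
    for g, ga in sorted(gt_comps.items()):
        for p, pa in sorted(pred_comps.items()):
            if ga & pa:
                out.append((g, p, dice(ga, pa)))
    return out


def exhaustive_best_matching(table, threshold):
    """Best one-to-one matching over pairs with dsc > threshold:
    maximal cardinality, then maximal total DSC. Exponential enumeration —
    only for tiny tables."""
    cand = [(g, p, d) for g, p, d in table if d > threshold]
    gids = sorted({g for g, _, _ in cand})
    pids = sorted({p for _, p, _ in cand})
    w = {(g, p): d for g, p, d in cand}
    best = []
    best_key = (0, 0.0)
    k = min(len(gids), len(pids))
    for size in range(k, 0, -1):
        for gsub in combinations(gids, size):
            for psub in permutations(pids, size):
                if all((g, p) in w for g, p in zip(gsub, psub)):
                    total = sum(w[(g, p)] for g, p in zip(gsub, psub))
                    if (size, total) > best_key:
                        best_key = (size, total)
                        best = list(zip(gsub, psub))
        if best_key[0] == size:  # any larger matching was impossible
            break
    return best, best_key


def brute_patient_metrics(gt_mask, pred_mask, connectivity=26, threshold=0.1):
    """All six per-patient metrics from sets and exhaustive matching."""
    gt_comps = {i + 1: c for i, c in enumerate(flood_fill_components(gt_mask, connectivity))}
    pred_comps = {i + 1: c for i, c in enumerate(flood_fill_components(pred_mask, connectivity))}
    table = brute_overlap_table(gt_comps, pred_comps)
    pairs, _ = exhaustive_best_matching(table, threshold)
    tp = len(pairs)
    fp = len(pred_comps) - tp
    fn = len(gt_comps) - tp
    ppv = tp / (tp + fp) if tp + fp else 1.0
    sn = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 1.0
    g2p = dict(pairs)
    p2g = {p: g for g, p in pairs}
    dscs, sns = [], []
    for g, ga in sorted(gt_comps.items()):
        if g in g2p:
            pa = pred_comps[g2p[g]]
            dscs.append(dice(ga, pa))
            sns.append(len(ga & pa) / len(ga))
        else:
            dscs.append(0.0)
            sns.append(0.0)
    ppvs = []
    for p, pa in sorted(pred_comps.items()):
        if p in p2g:
            ga = gt_comps[p2g[p]]
            ppvs.append(len(ga & pa) / len(pa))
        else:
            ppvs.append(0.0)
    lw_dsc = float(np.mean(dscs)) if dscs else 1.0
    lw_sn = float(np.mean(sns)) if sns else 1.0
    lw_ppv = float(np.mean(ppvs)) if ppvs else 1.0
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "inst_ppv": ppv, "inst_sn": sn, "inst_f1": f1,
        "lw_dsc": lw_dsc, "lw_ppv": lw_ppv, "lw_sn": lw_sn,
    }


def brute_mwu_two_sided(a, b):
    """Exact two-sided Mann–Whitney p by enumerating group assignments of
    the pooled sample (midrank U; deviation-from-mean two-sided rule)."""
    a = list(a)
    b = list(b)
    pooled = np.array(a + b, dtype=float)
    n_a = len(a)
    mu = n_a * len(b) / 2.0

    def u_of(ga, gb):
        ga = np.asarray(ga, dtype=float)
        gb = np.asarray(gb, dtype=float)
        return (ga[:, None] > gb[None, :]).sum() + 0.5 * (ga[:, None] == gb[None, :]).sum()

    u_obs = u_of(a, b)
    hits = total = 0
    for idx in combinations(range(pooled.size), n_a):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(idx)] = True
        u = u_of(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total
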