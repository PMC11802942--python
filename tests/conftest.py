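from __future__ import annotations

import numpy as np
import pytest

from lesionwise import LabelVolume
from lesionwise.instances import InstanceMap, InstanceRecord


def make_volume(arr, spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    return LabelVolume(np.asarray(arr, dtype=np.uint8), spacing)


def imap_from_counts(counts: dict[int, int], spacing=(1.0, 1.0, 1.0)) -> InstanceMap:
    """An InstanceMap with the given instance sizes laid out along one axis
    (geometry irrelevant: for feeding precomputed overlap tables)."""
    total = sum(counts.values())
    labels = np.zeros((total + len(counts), 1, 1), dtype=np.int32)
    pos = 0
    records = []
    vox_cm3 = float(np.prod(spacing)) / 1000.0
    for i, n in sorted(counts.items()):
        labels[pos : pos + n, 0, 0] = i
        pos += n + 1
        records.append(InstanceRecord(i, n, n * vox_cm3))
    return InstanceMap(labels, records, spacing)


def random_mask_pair(rng: np.random.Generator, shape=(18, 18, 18), n_lesions=None):
    """A small GT/prediction pair of well-separated blobs: each GT blob gets
    either a jittered copy, a shifted partial copy, or is dropped; extra
    false-positive blobs are added. Overlaps are one-to-one by construction.
    """
    gt = np.zeros(shape, dtype=np.uint8)
    pred = np.zeros(shape, dtype=np.uint8)
    if n_lesions is None:
        n_lesions = int(rng.integers(0, 4))
    # place blobs on a coarse lattice so they never touch
    cells = [(x, y, z) for x in range(3) for y in range(3) for z in range(3)]
    rng.shuffle(cells)
    n_fp = int(rng.integers(0, 3))
    for i in range(n_lesions + n_fp):
        cx, cy, cz = (6 * c + 1 for c in cells[i])
        sx, sy, sz = (int(rng.integers(1, 4)) for _ in range(3))
        is_fp = i >= n_lesions
        if not is_fp:
            gt[cx : cx + sx, cy : cy + sy, cz : cz + sz] = 1
            fate = rng.random()
            if fate < 0.25:
                continue  # missed lesion
            dx = int(rng.integers(0, 2))
            pred[cx + dx : cx + dx + sx, cy : cy + sy, cz : cz + sz] = 1
        else:
            pred[cx : cx + sx, cy : cy + sy, cz : cz + sz] = 1
    return make_volume(gt), make_volume(pred)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
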