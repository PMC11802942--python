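"""Binary label volumes and NIfTI I/O.

A :class:`LabelVolume` is one patient's 3D binary lesion mask together with
its voxel geometry (spacing in mm, affine). Ground-truth masks and model
predictions for the same patient must share a grid; no resampling is
performed here — co-registration is the caller's responsibility.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["LabelVolume", "read_label_volume", "write_label_volume"]


@dataclass
class LabelVolume:
    """A 3D binary mask with voxel geometry.

    Parameters
    ----------
    voxels : ndarray of {0, 1}, shape (nx, ny, nz)
        Binary lesion mask.
    spacing_mm : tuple of 3 floats
        Voxel edge lengths in mm.
    affine : (4, 4) ndarray, optional
        Voxel-to-world transform. Carried through to outputs; only the
        spacing is interpreted. Defaults to ``diag(spacing, 1)`` (RAS).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {vox.shape}")
        bad = np.setdiff1d(np.unique(vox), [0, 1])
        if bad.size:
            raise ValueError(
                f"mask is not binary; offending values: {bad.tolist()[:10]}"
            )
        self.voxels = vox.astype(np.uint8, copy=False)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if self.affine is None:
            self.affine = np.diag((*self.spacing_mm, 1.0))
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def foreground_voxel_count(self) -> int:
        return int(self.voxels.sum())


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI mask, coercing a single foreground value to 1.

    Files with exactly two distinct values ``{0, v}`` (or only zeros, or a
    single nonzero constant) are accepted and binarized. Files with more
    than two distinct values are rejected: they are likely multi-structure
    exports (e.g. stacked GTV/CTV/PTV layers) and must be binarized
    explicitly by the caller first.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    values = np.unique(data)
    nonzero = values[values != 0]
    if nonzero.size > 1:
        raise ValueError(
            f"{path} contains {values.size} distinct values {values.tolist()[:6]}; "
            "expected a binary mask {0, v}. Binarize explicitly (e.g. select one "
            "structure) before evaluation."
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume((data != 0).astype(np.uint8), spacing, np.asarray(img.affine))


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write a mask as NIfTI-1 (.nii or .nii.gz), byte-deterministically.

    Gzip output is written with a zeroed mtime so identical volumes always
    produce identical files.
    """
    path = Path(path)
    img = nib.Nifti1Image(vol.voxels.astype(np.uint8), vol.affine)
    img.header.set_zooms(vol.spacing_mm)
    raw = img.to_bytes()
    try:
        if path.name.endswith(".gz"):
            path.write_bytes(gzip.compress(raw, compresslevel=6, mtime=0))
        else:
            path.write_bytes(raw)
    except OSError as exc:
        raise OSError(f"failed to write label volume to {path}: {exc}") from exc
    return path
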