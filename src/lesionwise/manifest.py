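"""Cohort manifest handling.

A manifest maps patient IDs to their mask files: one or two ground-truth
masks (keys ``haq`` and optionally ``naq``) and one prediction file per
model name. Manifests are JSON; relative paths resolve against the
manifest's directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["CohortManifest", "load_manifest"]

_RESERVED_KEYS = {"haq", "naq"}


@dataclass
class PatientEntry:
    patient_id: str
    files: dict[str, Path]  # role ('haq', 'naq' or model name) -> path


@dataclass
class CohortManifest:
    patients: list[PatientEntry]
    root: Path
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids in manifest: {dupes}")

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def model_names(self) -> list[str]:
        names: list[str] = []
        for p in self.patients:
            for k in p.files:
                if k not in _RESERVED_KEYS and k not in names:
                    names.append(k)
        return names

    def path(self, patient_id: str, role: str) -> Path:
        entry = next((p for p in self.patients if p.patient_id == patient_id), None)
        if entry is None:
            raise KeyError(f"unknown patient {patient_id!r}")
        if role not in entry.files:
            raise KeyError(f"patient {patient_id!r} has no file for role {role!r}")
        return entry.files[role]


def load_manifest(path: str | Path) -> CohortManifest:
    """Load a manifest JSON and verify that every referenced file exists."""
    path = Path(path)
    data = json.loads(path.read_text())
    root = path.parent
    patients = []
    missing = []
    for rec in data["patients"]:
        files = {}
        for role, fname in rec["files"].items():
            p = root / fname
            if not p.exists():
                missing.append(str(p))
            files[role] = p
        patients.append(PatientEntry(rec["patient_id"], files))
    if missing:
        raise FileNotFoundError(
            f"manifest {path} references {len(missing)} missing file(s), "
            f"e.g. {missing[:3]}"
        )
    meta = {k: v for k, v in data.items() if k != "patients"}
    return CohortManifest(patients, root, meta)
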