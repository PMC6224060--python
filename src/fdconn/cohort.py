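"""Subject records and delimited cohort input/output.

A cohort is a list of :class:`SubjectRecord`: one 94x94 correlation matrix
plus sex ("M"/"F") and age in years.  On disk a cohort is a manifest
(subject_id, sex, age, path) pointing at one delimited matrix file per
subject, the format every pipeline stage consumes and emits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SEXES = ("M", "F")


@dataclass
class SubjectRecord:
    """One subject: metadata and symmetric correlation matrix F in [-1, 1]."""

    subject_id: str
    sex: str
    age: int
    F: np.ndarray

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[0] != self.F.shape[1]:
            raise ValueError(f"correlation matrix not square: {self.F.shape}")


def write_matrix(path, M: np.ndarray) -> None:
    np.savetxt(path, np.asarray(M), delimiter=",", fmt="%.10g")


def read_matrix(path) -> np.ndarray:
    M = np.loadtxt(path, delimiter=",")
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got shape {M.shape}")
    return M


def write_cohort(subjects: list[SubjectRecord], out_dir) -> Path:
    """Write per-subject matrices and a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        fname = f"{s.subject_id}.csv"
        write_matrix(out_dir / fname, s.F)
        rows.append({"subject_id": s.subject_id, "sex": s.sex, "age": s.age, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[SubjectRecord]:
    """Load a cohort from a manifest; matrix paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    missing = {"subject_id", "sex", "age", "path"} - set(table.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    base = manifest_path.parent
    subjects = []
    for row in table.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        subjects.append(
            SubjectRecord(str(row.subject_id), str(row.sex), int(row.age), read_matrix(p))
        )
    return subjects
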