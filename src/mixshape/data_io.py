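"""Ingestion and export of subjects x voxels matrices, group tables and results.

The central container is :class:`SubjectVoxelMatrix`: one row per subject,
one column per voxel, every subject measured on the same voxel set.  Voxels
that are non-finite for *any* subject are dropped for *all* subjects
(complete-case by voxel), because the pooled mixture model and the voxelwise
standardization both need per-voxel statistics over the full cohort.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectVoxelMatrix",
    "GroupAssignment",
    "read_matrix",
    "read_group_table",
    "read_nifti_cohort",
    "write_tables",
    "ResultBundle",
]


@dataclass
class SubjectVoxelMatrix:
    """n subjects x N voxels of scalar measurements (raw or standardized).

    Parameters
    ----------
    values
        Float matrix of shape ``(n, N)``; must be finite after ingestion.
    subject_ids
        Unique identifiers, one per row.
    standardized
        Whether values have been voxelwise z-scored.
    voxel_ids
        Optional column labels; generated as ``v000..`` when absent.
    n_dropped_voxels
        Count of voxels removed at ingestion/standardization, for the log.
    """

    values: np.ndarray
    subject_ids: list[str]
    standardized: bool = False
    voxel_ids: list[str] | None = None
    n_dropped_voxels: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x voxels) matrix")
        n, N = self.values.shape
        if n < 2 or N < 2:
            raise ValueError(f"need at least 2 subjects and 2 voxels, got {n}x{N}")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match number of rows")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject id")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries remain after ingestion")
        if self.voxel_ids is None:
            self.voxel_ids = [f"v{j:06d}" for j in range(N)]
        elif len(self.voxel_ids) != N:
            raise ValueError("voxel_ids length does not match number of columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupAssignment:
    """Mapping subject_id -> group label, with a fixed reporting order."""

    mapping: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty group assignment")
        seen: list[str] = []
        for g in self.mapping.values():
            if g not in seen:
                seen.append(g)
        if not self.group_order:
            self.group_order = seen
        missing = set(seen) - set(self.group_order)
        if missing:
            raise ValueError(f"groups missing from group_order: {sorted(missing)}")

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def labels_for(self, subject_ids: Sequence[str]) -> list[str]:
        try:
            return [self.mapping[s] for s in subject_ids]
        except KeyError as exc:  # pragma: no cover - message formatting
            raise ValueError(f"subject {exc.args[0]!r} has no group assignment") from exc

    def validate_against(self, matrix: SubjectVoxelMatrix) -> None:
        """Every subject in the matrix must appear exactly once; groups non-empty."""
        matrix_ids = set(matrix.subject_ids)
        assigned = set(self.mapping)
        if matrix_ids - assigned:
            raise ValueError(f"subjects without group: {sorted(matrix_ids - assigned)}")
        for g in self.group_order:
            if not any(s in matrix_ids for s in self.members(g)):
                raise ValueError(f"group {g!r} has no subjects in the matrix")


def _infer_sep(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "tsv"):
            raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'tsv'")
        return "," if fmt == "csv" else "\t"
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_matrix(path: str | Path, fmt: str | None = None) -> SubjectVoxelMatrix:
    """Read a subjects x voxels table (first column = subject id).

    Columns containing any non-numeric or non-finite value are removed for
    all subjects and the drop count is logged.
    """
    sep = _infer_sep(path, fmt)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("matrix file needs a subject id column plus voxel columns")
    subject_ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject id in matrix file")
    body = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    values = body.to_numpy(dtype=float)
    keep = np.all(np.isfinite(values), axis=0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d voxel column(s) with non-finite values", n_dropped)
    values = values[:, keep]
    voxel_ids = [c for c, k in zip(body.columns, keep) if k]
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError(
            f"need at least 2 subjects and 2 usable voxels, got "
            f"{values.shape[0]}x{values.shape[1]}"
        )
    return SubjectVoxelMatrix(
        values=values,
        subject_ids=subject_ids,
        standardized=False,
        voxel_ids=[str(c) for c in voxel_ids],
        n_dropped_voxels=n_dropped,
    )


def read_group_table(path: str | Path) -> GroupAssignment:
    """Read a CSV with columns ``subject_id`` and ``group``."""
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "subject_id" not in cols or "group" not in cols:
        raise ValueError("group table needs columns 'subject_id' and 'group'")
    sid = df[cols["subject_id"]].astype(str)
    if sid.duplicated().any():
        raise ValueError("duplicate subject id in group table")
    mapping = dict(zip(sid, df[cols["group"]].astype(str)))
    return GroupAssignment(mapping=mapping)


def read_nifti_cohort(
    volume_paths: Sequence[str | Path],
    mask_path: str | Path,
    subject_ids: Sequence[str] | None = None,
) -> SubjectVoxelMatrix:
    """Assemble the matrix from per-subject 3-D NIfTI volumes and a binary mask.

    Voxel columns are the mask's nonzero voxels in Fortran (x-fastest) linear
    order, identical for every subject, so results are reproducible across
    runs and platforms.
    """
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj)
    if mask.ndim != 3:
        raise ValueError(f"mask {mask_path} is not 3-D (shape {mask.shape})")
    idx = np.flatnonzero(mask.ravel(order="F") != 0)
    if idx.size == 0:
        raise ValueError("empty mask: no nonzero voxels")
    rows = []
    for p in volume_paths:
        img = nib.load(str(p))
        vol = np.asanyarray(img.dataobj, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError(
                f"dimension mismatch: volume {p} has shape {vol.shape}, "
                f"mask has shape {mask.shape}"
            )
        rows.append(vol.ravel(order="F")[idx])
    if subject_ids is None:
        subject_ids = [Path(p).name.split(".")[0] for p in volume_paths]
    values = np.vstack(rows)
    keep = np.all(np.isfinite(values), axis=0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d masked voxel(s) with non-finite values", n_dropped)
    return SubjectVoxelMatrix(
        values=values[:, keep],
        subject_ids=list(subject_ids),
        standardized=False,
        voxel_ids=[f"vox{j}" for j, k in zip(idx, keep) if k],
        n_dropped_voxels=n_dropped,
    )


@dataclass
class ResultBundle:
    """Everything a pipeline run can emit; any field may be None."""

    fit_params: pd.DataFrame | None = None
    aic_table: pd.DataFrame | None = None
    subject_mixing: pd.DataFrame | None = None
    group_mixing: pd.DataFrame | None = None
    tests: pd.DataFrame | None = None


_FLOAT_FMT = "%.12g"  # >= 10 significant digits so re-reading round-trips


def write_tables(results: ResultBundle, out_dir: str | Path) -> list[Path]:
    """Write every non-empty table of `results` as CSV; return written paths."""
    out_dir = Path(out_dir)
    tables = {
        "fit_params.csv": results.fit_params,
        "aic_table.csv": results.aic_table,
        "subject_mixing.csv": results.subject_mixing,
        "group_mixing.csv": results.group_mixing,
        "tests.csv": results.tests,
    }
    tables = {name: t for name, t in tables.items() if t is not None and len(t)}
    if not tables:
        raise ValueError("nothing to write: result container is empty")
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir} is not writable")
    written = []
    for name, table in tables.items():
        path = out_dir / name
        table.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)
    return written
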