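"""Voxelwise standardization of raw measurements across subjects.

Scalar imaging measures such as fractional anisotropy are strongly
heterogeneous across brain regions (deep white matter runs high, peripheral
white matter low).  Before pooling all voxels of all subjects into one
mixture fit, each voxel column is therefore z-scored across subjects:

    z_ij = (x_ij - mean_j) / sd_j

with the per-voxel sample mean and sample standard deviation (n-1
denominator) taken over the n subjects.  This removes per-voxel location and
scale so that what remains to model is the cross-subject shape structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import SubjectVoxelMatrix

logger = logging.getLogger(__name__)

__all__ = ["VoxelStats", "standardize"]


@dataclass
class VoxelStats:
    """Per-voxel mean and sample standard deviation used for standardization."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask over the input columns (zero-variance removed)

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have equal length")
        if np.any(self.sd <= 0):
            raise ValueError("retained voxels must have sd > 0")


def standardize(X: SubjectVoxelMatrix) -> tuple[SubjectVoxelMatrix, VoxelStats]:
    """Voxelwise z-score `X` across subjects.

    Zero-variance voxels (constant across the cohort, e.g. mask background)
    cannot be standardized and are removed for all subjects, with the count
    logged and recorded on the returned matrix.

    Returns
    -------
    (standardized matrix, VoxelStats)
        Output columns have sample mean 0 and sample sd 1.
    """
    if X.standardized:
        raise ValueError("matrix is already standardized")
    if X.n_subjects < 2:
        raise ValueError("standardization needs at least 2 subjects")
    mean = X.values.mean(axis=0)
    sd = X.values.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("no variable voxels: every column has zero variance")
    if n_dropped:
        logger.info("dropped %d zero-variance voxel column(s)", n_dropped)
    z = (X.values[:, keep] - mean[keep]) / sd[keep]
    if z.shape[1] < 2:
        raise ValueError("fewer than 2 variable voxels remain")
    out = SubjectVoxelMatrix(
        values=z,
        subject_ids=list(X.subject_ids),
        standardized=True,
        voxel_ids=[v for v, k in zip(X.voxel_ids, keep) if k],
        n_dropped_voxels=X.n_dropped_voxels + n_dropped,
    )
    stats = VoxelStats(mean=mean[keep], sd=sd[keep], kept=keep)
    return out, stats
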