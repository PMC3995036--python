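"""Synthetic cohorts with the statistical structure the method assumes.

A cohort is generated in three layers:

1. *Subject mixing probabilities.*  Each subject's tau_i is a logistic-normal
   perturbation of its group's mean mixing vector: independent Gaussian noise
   with standard deviation ``subject_tau_sd`` is added to the log-weights and
   the result re-normalized through a softmax, which keeps tau_i on the
   simplex.  Setting ``subject_tau_sd = 0`` gives every subject its group's
   tau exactly.
2. *Standardized-truth values.*  For each voxel a latent component label is
   drawn with probabilities tau_i, then z_ij ~ Normal(mu_k, sigma^2).  These
   are exact draws from the shared-component mixture, so they serve as ground
   truth for the fit.
3. *Raw-scale heterogeneity.*  The raw value is an affine distortion
   x_ij = a_j + b_j z_ij with per-voxel offsets a_j ~ Normal(0, voxel_offset_sd)
   and scales b_j ~ Uniform(voxel_scale_range), emulating regional
   location/scale differences (e.g. deep vs peripheral white-matter FA) that
   voxelwise standardization is meant to remove.

Everything is reproducible from the config's single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import GroupAssignment, SubjectVoxelMatrix

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "scenario_presets",
    "write_cohort",
]

# Component geometry used by the FA-like presets: two Gaussian densities at
# moderate separation (|mu2 - mu1| / sigma ~ 1.2) on the standardized scale.
_FA_MU = (-0.26, 0.78)
_FA_SIGMA = 0.87


@dataclass
class SyntheticCohortConfig:
    """Ground-truth generative settings for one simulated cohort."""

    mu: tuple[float, ...] = _FA_MU
    sigma: float = _FA_SIGMA
    group_mean_tau: tuple[tuple[float, ...], ...] = (
        (0.7277, 0.2723),
        (0.7337, 0.2663),
        (0.7481, 0.2519),
        (0.7873, 0.2127),
    )
    subject_tau_sd: float = 0.2        # sd of log-weight perturbation
    n_per_group: tuple[int, ...] = (7, 7, 7, 7)
    n_voxels: int = 20_000
    voxel_offset_sd: float = 0.5
    voxel_scale_range: tuple[float, float] = (0.8, 1.25)
    seed: int = 0
    group_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim != 1 or (mu.size > 1 and not np.all(np.diff(mu) > 0)):
            raise ValueError("mu must be strictly ascending")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        gt = np.asarray(self.group_mean_tau, dtype=float)
        if gt.ndim != 2 or gt.shape[1] != mu.size:
            raise ValueError("group_mean_tau must be G x m")
        if np.any(gt < 0) or np.any(np.abs(gt.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("each group_mean_tau row must be a probability vector")
        if len(self.n_per_group) != gt.shape[0]:
            raise ValueError("n_per_group length must match number of groups")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("each group needs at least one subject")
        if self.subject_tau_sd < 0 or self.voxel_offset_sd < 0:
            raise ValueError("dispersions must be non-negative")
        lo, hi = self.voxel_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("voxel_scale_range must be 0 < lo <= hi")
        if self.group_labels is not None and len(self.group_labels) != gt.shape[0]:
            raise ValueError("group_labels length must match number of groups")

    @property
    def m(self) -> int:
        return len(self.mu)

    @property
    def n_groups(self) -> int:
        return len(self.n_per_group)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth."""

    raw: SubjectVoxelMatrix
    standardized_truth: SubjectVoxelMatrix
    true_subject_tau: np.ndarray       # (n, m)
    true_labels: np.ndarray            # (n, N) component index per observation
    groups: GroupAssignment
    config: SyntheticCohortConfig


def _logistic_normal(rng: np.random.Generator, mean_tau: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0:
        return mean_tau.copy()
    logw = np.log(mean_tau) + rng.normal(0.0, sd, size=mean_tau.size)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw one cohort from `config` (fully reproducible from ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    mu = np.asarray(config.mu, dtype=float)
    gt = np.asarray(config.group_mean_tau, dtype=float)
    n, N, m = config.n_subjects, config.n_voxels, config.m

    labels_g = config.group_labels or tuple(
        f"group{g + 1}" for g in range(config.n_groups)
    )
    subject_ids, group_of, tau_rows = [], {}, []
    for g, (lab, ng) in enumerate(zip(labels_g, config.n_per_group)):
        for s in range(ng):
            sid = f"{lab}_s{s + 1}"
            subject_ids.append(sid)
            group_of[sid] = lab
            tau_rows.append(_logistic_normal(rng, gt[g], config.subject_tau_sd))
    true_tau = np.vstack(tau_rows)

    # component label per (subject, voxel) by inverse-CDF on subject tau
    u = rng.random((n, N))
    cum = np.cumsum(true_tau, axis=1)
    labels = (u[:, :, None] > cum[:, None, :-1]).sum(axis=2) if m > 1 else np.zeros(
        (n, N), dtype=int
    )
    z = rng.normal(mu[labels], config.sigma)

    a = rng.normal(0.0, config.voxel_offset_sd, size=N)
    b = rng.uniform(*config.voxel_scale_range, size=N)
    x = a[None, :] + b[None, :] * z

    groups = GroupAssignment(mapping=group_of, group_order=list(labels_g))
    raw = SubjectVoxelMatrix(values=x, subject_ids=list(subject_ids))
    truth = SubjectVoxelMatrix(
        values=z, subject_ids=list(subject_ids), standardized=True
    )
    return SyntheticCohort(
        raw=raw,
        standardized_truth=truth,
        true_subject_tau=true_tau,
        true_labels=labels.astype(np.int8),
        groups=groups,
        config=config,
    )


def scenario_presets() -> dict[str, SyntheticCohortConfig]:
    """Named study scenarios.

    - ``paper_like``: four age-group-like cohorts of 7 subjects, FA-like
      component geometry and group mixing probabilities, 20,000 voxels.
    - ``null``: identical mixing probabilities in every group (no group
      effect), for test calibration.
    - ``separable``: widely separated components (mu = +/-3, sigma = 1) where
      order selection should be unambiguous.
    """
    base = SyntheticCohortConfig()
    return {
        "paper_like": base,
        "null": replace(
            base,
            group_mean_tau=tuple(((0.7488, 0.2512),) * 4),
        ),
        "separable": replace(
            base,
            mu=(-3.0, 3.0),
            sigma=1.0,
            group_mean_tau=tuple(((0.5, 0.5),) * 4),
        ),
    }


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the CSV formats the ingestion layer reads.

    Emits ``matrix.csv`` (raw values), ``groups.csv``, and truth tables
    ``true_subject_tau.csv`` and ``true_params.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = cohort.raw
    mat = pd.DataFrame(raw.values, columns=raw.voxel_ids)
    mat.insert(0, "subject_id", raw.subject_ids)
    paths = {"matrix": out_dir / "matrix.csv"}
    mat.to_csv(paths["matrix"], index=False, float_format="%.12g")

    gdf = pd.DataFrame(
        {
            "subject_id": raw.subject_ids,
            "group": cohort.groups.labels_for(raw.subject_ids),
        }
    )
    paths["groups"] = out_dir / "groups.csv"
    gdf.to_csv(paths["groups"], index=False)

    tdf = pd.DataFrame(
        cohort.true_subject_tau,
        columns=[f"tau_{k + 1}" for k in range(cohort.config.m)],
    )
    tdf.insert(0, "subject_id", raw.subject_ids)
    paths["true_subject_tau"] = out_dir / "true_subject_tau.csv"
    tdf.to_csv(paths["true_subject_tau"], index=False, float_format="%.12g")

    pdf = pd.DataFrame(
        {
            "component": np.arange(1, cohort.config.m + 1),
            "mu": cohort.config.mu,
            "sigma": cohort.config.sigma,
        }
    )
    paths["true_params"] = out_dir / "true_params.csv"
    pdf.to_csv(paths["true_params"], index=False, float_format="%.12g")
    return paths
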