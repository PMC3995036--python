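"""Subject- and group-level density functions recovered a posteriori.

Once the pooled mixture is fit, every observation z_ij gets a posterior
membership probability tau_ij(k) by Bayes' theorem.  Averaging memberships
over a subject's voxels gives that subject's mixing probabilities tau_i(k);
averaging those over a group's subjects gives the group's tau*_g(k).  Because
the Gaussian components phi_k are shared, a subject's (or group's) density is
the component mixture re-weighted by its own tau — so groups differ only in
how much weight they place on the shared components, and those weights are
directly comparable and testable.

Standard errors of tau*_g(k) are the between-subject sample standard
deviation of tau_i(k) within the group divided by sqrt(n_g); subjects are the
unit of analysis.  A singleton group has no between-subject spread and its
s.e. is reported as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GroupAssignment, SubjectVoxelMatrix
from .gmm import GMMParams, e_step, mixture_density

__all__ = [
    "MixingProfile",
    "membership",
    "subject_mixing",
    "group_mixing",
    "density_curve",
    "compute_profile",
    "default_grid",
]


@dataclass
class MixingProfile:
    """Subject- and group-level mixing probabilities for one fitted mixture."""

    subject_ids: list[str]
    subject_groups: list[str]
    subject_tau: np.ndarray       # (n, m)
    group_labels: list[str]
    group_tau: np.ndarray         # (G, m)
    group_se: np.ndarray          # (G, m); NaN for singleton groups
    params: GMMParams

    def subject_frame(self) -> pd.DataFrame:
        m = self.params.m
        df = pd.DataFrame(
            {"subject_id": self.subject_ids, "group": self.subject_groups}
        )
        for k in range(m):
            df[f"tau_{k + 1}"] = self.subject_tau[:, k]
        return df

    def group_frame(self) -> pd.DataFrame:
        m = self.params.m
        df = pd.DataFrame({"group": self.group_labels})
        for k in range(m):
            df[f"tau_{k + 1}"] = self.group_tau[:, k]
        for k in range(m):
            df[f"se_{k + 1}"] = self.group_se[:, k]
        return df


def membership(z, params: GMMParams) -> np.ndarray:
    """Posterior membership probabilities tau_ij(k) = tau(k)phi_k(z)/f(z).

    Scalar input gives a length-m vector; array input appends a trailing
    component axis.
    """
    out = e_step(np.atleast_1d(np.asarray(z, dtype=float)), params)
    return out[0] if np.ndim(z) == 0 else out


def subject_mixing(memberships: np.ndarray) -> np.ndarray:
    """Voxel-average memberships per subject: tau_i(k) = (1/N) sum_j tau_ij(k)."""
    memberships = np.asarray(memberships, dtype=float)
    if memberships.ndim != 3:
        raise ValueError("memberships must be (n, N, m)")
    return memberships.mean(axis=1)


def group_mixing(
    subject_tau: np.ndarray,
    groups: GroupAssignment,
    subject_ids: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Group means and standard errors of the subject mixing probabilities.

    Returns (tau*, se) each shaped (G, m), rows following `groups.group_order`.
    se uses the n_g - 1 denominator sd over subjects divided by sqrt(n_g),
    and is NaN when n_g = 1.
    """
    subject_tau = np.asarray(subject_tau, dtype=float)
    unknown = [s for s in subject_ids if s not in groups.mapping]
    if unknown:
        raise ValueError(f"subjects without group assignment: {unknown}")
    labels = np.asarray(groups.labels_for(subject_ids))
    G, m = groups.n_groups, subject_tau.shape[1]
    tau_g = np.empty((G, m))
    se_g = np.full((G, m), np.nan)
    for gi, g in enumerate(groups.group_order):
        idx = np.flatnonzero(labels == g)
        if idx.size == 0:
            raise ValueError(f"group {g!r} has no subjects")
        rows = subject_tau[idx]
        tau_g[gi] = rows.mean(axis=0)
        if idx.size > 1:
            se_g[gi] = rows.std(axis=0, ddof=1) / np.sqrt(idx.size)
    return tau_g, se_g


def density_curve(tau, params: GMMParams, grid) -> np.ndarray:
    """Evaluate sum_k tau(k) phi_k(z) / sigma on `grid` for any simplex tau."""
    tau = np.asarray(tau, dtype=float)
    if abs(float(tau.sum()) - 1.0) > 1e-8:
        raise ValueError("tau must sum to 1")
    p = GMMParams(mu=params.mu, sigma=params.sigma, tau=tau)
    return np.asarray(mixture_density(np.asarray(grid, dtype=float), p))


def default_grid(Z, params: GMMParams, n_points: int = 512) -> np.ndarray:
    """Evaluation grid spanning the data range padded by 4 sigma."""
    z = Z.values if isinstance(Z, SubjectVoxelMatrix) else np.asarray(Z)
    lo = float(z.min()) - 4.0 * params.sigma
    hi = float(z.max()) + 4.0 * params.sigma
    return np.linspace(lo, hi, n_points)


def compute_profile(
    Z: SubjectVoxelMatrix,
    params: GMMParams,
    groups: GroupAssignment,
) -> MixingProfile:
    """Full a-posteriori profile: memberships -> subject tau -> group tau/se.

    Memberships are recomputed from the final parameters, so the profile is a
    pure function of (data, params).
    """
    groups.validate_against(Z)
    resp = e_step(Z, params)
    s_tau = subject_mixing(resp)
    g_tau, g_se = group_mixing(s_tau, groups, Z.subject_ids)
    return MixingProfile(
        subject_ids=list(Z.subject_ids),
        subject_groups=groups.labels_for(Z.subject_ids),
        subject_tau=s_tau,
        group_labels=list(groups.group_order),
        group_tau=g_tau,
        group_se=g_se,
        params=params,
    )
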