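"""Nonparametric comparison of subject-level mixing probabilities between groups.

Groups are compared on the subject-level mixing probabilities tau_i(k) with
the Kruskal-Wallis rank test (tie-corrected H statistic, chi-square
approximation with G - 1 degrees of freedom).  The main entry point runs one
two-group test per non-reference group against a reference group, plus the
all-groups omnibus test.  Pairwise p-values are reported raw, with an
optional Holm step-down adjustment column over the pairwise family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import GroupAssignment

__all__ = ["TestResult", "kruskal_wallis", "pairwise_vs_reference", "tests_table"]


@dataclass
class TestResult:
    """One Kruskal-Wallis comparison."""

    comparison: str
    component: int
    statistic: float
    df: int
    p_value: float
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if self.statistic < -1e-12:
            raise ValueError("H statistic must be non-negative")


def kruskal_wallis(values, groups, comparison: str = "", component: int = 0) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups.

    `values` is a flat sequence of observations and `groups` the matching
    group labels.  p comes from the chi-square approximation with G - 1
    degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValueError("values and groups must have equal length")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    samples = [values[labels == g] for g in uniq]
    if any(s.size == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.unique(values).size == 1:
        raise ValueError("degenerate ranks: all values identical")
    H, p = stats.kruskal(*samples)
    return TestResult(
        comparison=comparison or " vs ".join(str(g) for g in uniq),
        component=component,
        statistic=float(H),
        df=len(uniq) - 1,
        p_value=float(p),
        group_sizes={str(g): int(s.size) for g, s in zip(uniq, samples)},
    )


def pairwise_vs_reference(
    subject_tau: np.ndarray,
    groups: GroupAssignment,
    subject_ids: list[str],
    reference: str | None = None,
    component: int | None = None,
) -> list[TestResult]:
    """Two-group tests of tau_i(k) for each non-reference group, plus omnibus.

    Parameters
    ----------
    subject_tau
        (n, m) subject mixing probabilities.
    reference
        Reference group label; defaults to the first group in reporting order.
    component
        1-based component index k to test; defaults to m, the highest-mean
        component.

    Returns the pairwise results in group order followed by the omnibus
    all-groups test (df = G - 1).
    """
    subject_tau = np.asarray(subject_tau, dtype=float)
    n, m = subject_tau.shape
    if component is None:
        component = m
    if not 1 <= component <= m:
        raise ValueError(f"component {component} out of range 1..{m}")
    if reference is None:
        reference = groups.group_order[0]
    if reference not in groups.group_order:
        raise ValueError(f"reference group {reference!r} not found")
    labels = np.asarray(groups.labels_for(subject_ids))
    vals = subject_tau[:, component - 1]
    results = []
    for g in groups.group_order:
        if g == reference:
            continue
        sel = (labels == reference) | (labels == g)
        results.append(
            kruskal_wallis(
                vals[sel], labels[sel],
                comparison=f"{reference} vs {g}", component=component,
            )
        )
    results.append(
        kruskal_wallis(vals, labels, comparison="omnibus", component=component)
    )
    return results


def tests_table(results: list[TestResult], holm: bool = True) -> pd.DataFrame:
    """Tabulate test results; Holm adjustment spans the pairwise family only."""
    df = pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "component": [r.component for r in results],
            "H": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_raw": [r.p_value for r in results],
        }
    )
    if holm:
        pair = df["comparison"] != "omnibus"
        p_holm = np.full(len(df), np.nan)
        if pair.any():
            p_holm[pair.to_numpy()] = multipletests(
                df.loc[pair, "p_raw"], method="holm"
            )[1]
        df["p_holm"] = p_holm
    return df
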