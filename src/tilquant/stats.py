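"""Nonparametric statistical battery over per-case density profiles.

Density distributions across cases are heavily skewed, so group comparisons
use rank/median tests: Mann-Whitney U for two groups, Kruskal-Wallis with
pairwise median tests (Bonferroni-corrected) for more, a k-sample median
test (counts above/below the grand median, chi-square), Spearman rank
correlation for method agreement, and Kaplan-Meier / log-rank for survival.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparisonResult:
    grouping: str
    variable: str
    test: str  # "mann_whitney" | "kruskal_wallis"
    statistic: float
    p_value: float
    group_medians: dict
    group_sizes: dict
    #: pairwise post-hoc results (only for >2 groups): list of dicts with
    #: groups, test, statistic, p, adjusted p and the Bonferroni multiplier m.
    pairwise: list | None = None


def median_test_2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample median test: chi-square on counts above/at-or-below the
    pooled grand median."""
    stat, p, _, _ = sps.median_test(x, y, ties="below")
    return float(stat), float(p)


def compare_groups(
    values: pd.Series,
    groups: pd.Series,
    grouping: str = "group",
    variable: str = "density",
    posthoc: str = "median",
) -> GroupComparisonResult:
    """Compare a density variable across 2 or more groups.

    Two groups: Mann-Whitney U.  More: Kruskal-Wallis, followed by pairwise
    post-hoc tests (``median`` by default, ``dunn``-style rank tests via
    pairwise Mann-Whitney as an alternative) with Bonferroni adjustment
    ``p_adj = min(1, m * p)`` over the m pairs.  Constant data across all
    groups yields p = 1 by convention.
    """
    df = pd.DataFrame({"v": pd.to_numeric(values, errors="coerce"), "g": groups}).dropna()
    names = [g for g in pd.unique(df["g"])]
    samples = [df.loc[df["g"] == g, "v"].to_numpy() for g in names]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need at least two non-empty groups")
    medians = {g: float(np.median(s)) for g, s in zip(names, samples)}
    sizes = {g: int(len(s)) for g, s in zip(names, samples)}
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        test = "mann_whitney" if len(samples) == 2 else "kruskal_wallis"
        return GroupComparisonResult(grouping, variable, test, 0.0, 1.0, medians, sizes)
    if len(samples) == 2:
        stat, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return GroupComparisonResult(
            grouping, variable, "mann_whitney", float(stat), float(p), medians, sizes
        )
    stat, p = sps.kruskal(*samples)
    pairs = list(combinations(range(len(samples)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        xi, xj = samples[i], samples[j]
        if np.ptp(np.concatenate([xi, xj])) == 0:
            ps, pp = 0.0, 1.0
            name = posthoc
        elif posthoc == "median":
            ps, pp = median_test_2(xi, xj)
            name = "median"
        elif posthoc == "dunn":
            ps, pp = sps.mannwhitneyu(xi, xj, alternative="two-sided")
            name = "dunn"
        else:
            raise ValueError(f"unknown posthoc {posthoc!r}")
        pairwise.append(
            {
                "groups": (names[i], names[j]),
                "test": name,
                "statistic": float(ps),
                "p_value": float(pp),
                "adjusted_p": float(min(1.0, m * pp)),
                "bonferroni_m": m,
            }
        )
    return GroupComparisonResult(
        grouping, variable, "kruskal_wallis", float(stat), float(p), medians, sizes, pairwise
    )


def spearman_agreement(x, y) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) between paired counts,
    e.g. the same cores counted by two staining methods.  Constant input
    leaves rho undefined (NaN) and is flagged by the caller."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class SurvivalResult:
    endpoint: str
    grouping: str
    curves: dict  # group -> DataFrame(time, survival, at_risk)
    logrank_statistic: float
    logrank_p: float
    group_sizes: dict


def km_logrank(
    cohort: pd.DataFrame,
    group_col: str,
    time_col: str,
    event_col: str,
    endpoint: str = "RFS",
) -> SurvivalResult:
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    Groups with zero subjects are dropped with a warning-level note; the
    test requires at least two groups and one event overall.
    """
    df = cohort[[group_col, time_col, event_col]].dropna()
    df = df[df[time_col] >= 0]
    groups = [g for g in pd.unique(df[group_col]) if (df[group_col] == g).sum() > 0]
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    if df[event_col].sum() == 0:
        raise ValueError("log-rank needs at least one event")
    curves = {}
    sizes = {}
    for g in groups:
        sub = df[df[group_col] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], event_observed=sub[event_col])
        surv = kmf.survival_function_.reset_index()
        surv.columns = ["time", "survival"]
        at_risk = kmf.event_table["at_risk"].reindex(surv["time"]).to_numpy()
        surv["at_risk"] = at_risk
        curves[g] = surv
        sizes[g] = int(len(sub))
    res = multivariate_logrank_test(df[time_col], df[group_col], df[event_col])
    return SurvivalResult(
        endpoint=endpoint,
        grouping=group_col,
        curves=curves,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
        group_sizes=sizes,
    )


def median_split(values: pd.Series) -> pd.Series:
    """Dichotomize a density at its pooled median ("low" vs "high"), the
    first-pass grouping used for prognostic stratification."""
    v = pd.to_numeric(values, errors="coerce")
    med = float(np.nanmedian(v))
    out = pd.Series(
        np.where(v.isna(), None, np.where(v < med, "low", "high")), index=values.index
    )
    return out
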