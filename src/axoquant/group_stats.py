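"""Cohort statistics: one-way ANOVA with Tukey HSD post-hoc, recovery reports.

Animals are the unit of analysis: each animal contributes one value per
(measure, region), with multiple ROIs per animal averaged beforehand. Each
measure is tested independently with a classical one-way ANOVA followed by
Tukey's studentized-range post-hoc, mirroring standard practice for small
multi-group histology cohorts (sham / lesion / lesion+treatment designs,
n = 3-4 per group, significance at p < 0.05). Group summaries are reported
as mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "RecoveryReport",
    "one_way_anova",
    "tukey_hsd",
    "compare_groups",
    "compare_all_measures",
    "recovery_report",
]


@dataclass
class GroupComparison:
    measure: str
    region: str
    groups: list[str]
    means: list[float]
    sems: list[float]
    n: list[int]
    anova_f: float
    anova_p: float
    tukey: list[dict] = field(default_factory=list)  # group_a, group_b, mean_diff, p_adj

    def tukey_p(self, group_a: str, group_b: str) -> float:
        for row in self.tukey:
            if {row["group_a"], row["group_b"]} == {group_a, group_b}:
                return row["p_adj"]
        raise KeyError(f"no Tukey row for ({group_a}, {group_b})")


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has {len(g)} values; need at least 2")
    return groups


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA.

    F is the ratio of between-group to within-group mean squares; the
    p-value comes from the F distribution with (k-1, N-k) degrees of
    freedom. Identical groups give F = 0, p = 1.
    """
    groups = _check_groups(groups)
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n_total = int(ns.sum())
    grand = float(np.concatenate(groups).mean())
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0:
        f_stat = 0.0 if ms_between == 0 else float("inf")
    else:
        f_stat = ms_between / ms_within
    p = float(sps.f.sf(f_stat, df_b, df_w)) if np.isfinite(f_stat) else 0.0
    return float(f_stat), p


def tukey_hsd(groups: list, labels: list[str] | None = None) -> list[dict]:
    """Tukey's honestly-significant-difference test for all group pairs.

    For each unordered pair the studentized range statistic is
    q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) and the adjusted
    p-value is the survival function of the studentized range distribution
    with k groups and N-k error degrees of freedom. With two groups this
    reduces to the two-sample result via q = |t| * sqrt(2).
    """
    groups = _check_groups(groups)
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")
    ns = np.array([len(g) for g in groups])
    df_w = int(ns.sum()) - k
    ms_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups)) / df_w
    rows = []
    for i, j in combinations(range(k), 2):
        diff = float(groups[j].mean() - groups[i].mean())
        if ms_within == 0:
            q = 0.0 if diff == 0 else float("inf")
        else:
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
        rows.append(
            dict(
                group_a=labels[i], group_b=labels[j], mean_diff=diff,
                q=float(q), p_adj=min(max(p_adj, 0.0), 1.0),
            )
        )
    return rows


def compare_groups(
    values_by_group: dict[str, list[float]],
    measure: str = "",
    region: str = "",
) -> GroupComparison:
    """ANOVA + Tukey + mean/SEM summary for one measure."""
    labels = list(values_by_group)
    groups = [np.asarray(values_by_group[name], float) for name in labels]
    f_stat, p = one_way_anova(groups)
    return GroupComparison(
        measure=measure,
        region=region,
        groups=labels,
        means=[float(g.mean()) for g in groups],
        sems=[float(g.std(ddof=1) / np.sqrt(len(g))) for g in groups],
        n=[len(g) for g in groups],
        anova_f=f_stat,
        anova_p=p,
        tukey=tukey_hsd(groups, labels),
    )


def compare_all_measures(densities: pd.DataFrame) -> list[GroupComparison]:
    """Per-(measure, region) group comparison from a long-format density table.

    Multiple rows per animal within a (measure, region) — e.g. several ROIs —
    are averaged so the animal stays the unit of analysis.
    """
    out = []
    for (measure, region), sub in densities.groupby(["measure", "region"], sort=True):
        per_animal = sub.groupby(["group", "animal"], sort=False)["value"].mean()
        by_group = {
            g: per_animal.loc[g].tolist() for g in sub["group"].unique()
        }
        if len(by_group) < 2 or any(len(v) < 2 for v in by_group.values()):
            continue
        out.append(compare_groups(by_group, measure=measure, region=region))
    return out


@dataclass
class RecoveryReport:
    measure: str
    group: str
    true_multiplier: float
    estimated_ratio: float
    abs_error: float
    tolerance: float
    passed: bool


def recovery_report(
    densities: pd.DataFrame,
    multipliers: dict[str, float],
    reference_group: str,
    tolerance: float = 0.10,
    measures: list[str] | None = None,
) -> list[RecoveryReport]:
    """Estimated group/reference density ratios against constructed multipliers.

    For a simulated cohort, the ratio of group means should recover the
    effect multiplier applied by the generator; a report row passes when
    |estimated - true| <= ``tolerance`` (absolute, on the ratio scale).
    """
    if reference_group not in multipliers:
        raise ValueError(f"reference group {reference_group!r} not in multipliers")
    reports = []
    for measure, sub in densities.groupby("measure", sort=True):
        if measures is not None and measure not in measures:
            continue
        per_animal = sub.groupby(["group", "animal"], sort=False)["value"].mean()
        if reference_group not in per_animal.index.get_level_values(0):
            continue
        ref_mean = float(per_animal.loc[reference_group].mean())
        ref_mult = multipliers[reference_group]
        for group, mult in multipliers.items():
            if group == reference_group:
                continue
            if group not in per_animal.index.get_level_values(0):
                continue
            est = float(per_animal.loc[group].mean()) / ref_mean if ref_mean else float("nan")
            true = mult / ref_mult
            err = abs(est - true)
            reports.append(
                RecoveryReport(
                    measure=measure, group=group, true_multiplier=true,
                    estimated_ratio=est, abs_error=err, tolerance=tolerance,
                    passed=bool(err <= tolerance),
                )
            )
    return reports
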