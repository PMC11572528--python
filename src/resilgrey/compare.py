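"""Rank-based comparison of scores across covariate groups.

Composite scores are summarised nonparametrically (median, interquartile
range), so group differences are tested with rank methods: the Wilcoxon
rank-sum (Mann-Whitney U) test for two groups, the Kruskal-Wallis H test for
more, and pairwise rank-sum post-hoc tests with Bonferroni adjustment by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .survey import ResponseTable

__all__ = ["GroupComparisonResult", "compare_by_factor"]


@dataclass
class GroupComparisonResult:
    factor: str
    test: str  # which omnibus test was run
    statistic: float
    p_value: float
    group_summary: pd.DataFrame  # per group: n, median, iqr, q1, q3
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_adjusted
    adjustment: str = "bonferroni"
    notes: list[str] = field(default_factory=list)


def _summarise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, vals in groups.items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"group": name, "n": len(vals), "median": med,
                     "iqr": q3 - q1, "q1": q1, "q3": q3})
    return pd.DataFrame(rows).set_index("group")


def compare_by_factor(
    scores: pd.Series,
    table: ResponseTable,
    factor: str,
    adjustment: str = "bonferroni",
) -> GroupComparisonResult:
    """Omnibus and pairwise rank tests of scores across a covariate's levels.

    Two non-empty levels are compared with the two-sided rank-sum test;
    three or more with Kruskal-Wallis.  Ties are handled by average ranks
    with the usual normal/chi-square corrections (scipy defaults).  Levels
    with fewer than 2 members are excluded from pairwise testing and noted.
    """
    if factor not in table.covariates.columns:
        raise KeyError(f"covariate {factor!r} not present")
    labels = table.covariates[factor].reindex(scores.index)
    mask = labels.notna() & scores.notna()
    labels, vals = labels[mask], scores[mask]
    groups = {str(g): vals[labels == g].to_numpy(float) for g in labels.unique()}
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 non-empty groups")

    notes = []
    names = sorted(groups)
    if len(groups) == 2:
        a, b = (groups[n] for n in names)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    else:
        stat, p = stats.kruskal(*(groups[n] for n in names))
        test = "kruskal-wallis"

    testable = [n for n in names if len(groups[n]) >= 2]
    skipped = sorted(set(names) - set(testable))
    if skipped:
        notes.append(f"groups excluded from pairwise tests (n < 2): {skipped}")
    pairs = list(combinations(testable, 2))
    rows = []
    for ga, gb in pairs:
        s, pr = stats.mannwhitneyu(groups[ga], groups[gb], alternative="two-sided")
        rows.append({"group_a": ga, "group_b": gb, "statistic": float(s), "p_raw": float(pr)})
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw"])
    if len(pairwise):
        pairwise["p_adjusted"] = multipletests(pairwise["p_raw"], method=adjustment)[1]
    else:
        pairwise["p_adjusted"] = pd.Series(dtype=float)

    return GroupComparisonResult(
        factor=factor,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        group_summary=_summarise(groups),
        pairwise=pairwise,
        adjustment=adjustment,
        notes=notes,
    )
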