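"""Delphi-round statistics: Kendall's W and indicator screening.

Expert panels in a Delphi consultation rate the importance of candidate
indicators over several rounds.  Agreement within a round is measured by
Kendall's coefficient of concordance W on within-expert ranks (average ranks
for ties, with the standard tie correction), and indicators are screened
between rounds by mean importance and coefficient of variation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpertRatingRound",
    "ScreeningRule",
    "KendallWResult",
    "ScreeningResult",
    "kendalls_w",
    "screen_indicators",
]


@dataclass
class ExpertRatingRound:
    """Importance ratings from one Delphi round: experts x items."""

    round: int
    ratings: np.ndarray  # shape (n_experts, n_items)
    item_ids: list[str]

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.ratings.ndim != 2:
            raise ValueError("ratings must be a 2-D experts x items matrix")
        m, n = self.ratings.shape
        if m < 2 or n < 2:
            raise ValueError(f"need >=2 experts and >=2 items, got {m} x {n}")
        if len(self.item_ids) != n:
            raise ValueError("item_ids length must match the number of columns")

    @classmethod
    def from_csv(cls, path, round: int = 1) -> "ExpertRatingRound":
        """Rows = experts, columns = item ids."""
        df = pd.read_csv(path)
        if df.columns[0].lower() in ("expert", "expert_id"):
            df = df.set_index(df.columns[0])
        return cls(round=round, ratings=df.to_numpy(float), item_ids=list(df.columns))

    @property
    def n_experts(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_items(self) -> int:
        return self.ratings.shape[1]


@dataclass
class ScreeningRule:
    """Keep an indicator iff mean importance >= threshold and CV <= bound."""

    min_mean_importance: float = 3.5
    max_cv: float = 0.25

    def __post_init__(self) -> None:
        if self.max_cv <= 0:
            raise ValueError("max_cv must be positive")


@dataclass
class KendallWResult:
    W: float
    chi2: float
    df: int
    p: float
    n_experts: int
    n_items: int
    degenerate: bool = False  # every expert tied on all items: W undefined
    p_exact: float | None = None


@dataclass
class ScreeningResult:
    kept: list[str]
    dropped: list[str]
    per_item: pd.DataFrame  # columns: mean, sd, cv
    warning: str | None = None


def _rank_rows(ratings: np.ndarray) -> np.ndarray:
    """Within-expert average ranks (ties share the mean rank)."""
    return np.apply_along_axis(stats.rankdata, 1, ratings)


def _tie_correction(ranks_row: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups of one expert's ranks."""
    _, counts = np.unique(ranks_row, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kendalls_w(round_: ExpertRatingRound, exact_p_max_items: int = 0) -> KendallWResult:
    """Kendall's coefficient of concordance with tie correction.

    W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j), where S is the sum of squared
    deviations of item rank sums from their mean m(n+1)/2 and T_j is expert
    j's tie correction sum(t^3 - t).  Significance via the chi-square
    approximation chi2 = m (n - 1) W with n - 1 degrees of freedom; an exact
    permutation p-value over all expert-rank permutations is available for
    small item counts (``exact_p_max_items``) as a cross-check.
    """
    m, n = round_.n_experts, round_.n_items
    ranks = _rank_rows(round_.ratings)
    ties = sum(_tie_correction(ranks[j]) for j in range(m))
    col_sums = ranks.sum(axis=0)
    s = float(np.sum((col_sums - m * (n + 1) / 2.0) ** 2))
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:
        # all experts tied across every item: no ranking information
        return KendallWResult(
            W=float("nan"), chi2=float("nan"), df=n - 1, p=float("nan"),
            n_experts=m, n_items=n, degenerate=True,
        )
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    p = float(stats.chi2.sf(chi2, n - 1))
    result = KendallWResult(W=w, chi2=chi2, df=n - 1, p=p, n_experts=m, n_items=n)
    if 0 < n <= exact_p_max_items:
        result.p_exact = _exact_permutation_p(ranks, w)
    return result


def _exact_permutation_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact p by permuting each expert's ranks over items (small n only)."""
    m, n = ranks.shape
    if math.factorial(n) ** (m - 1) > 200_000:
        raise ValueError("exact permutation p-value infeasible for this size")
    perms = list(itertools.permutations(range(n)))
    # condition on expert 0's ranks: W is invariant to a common relabeling
    count = total = 0
    ties = sum(_tie_correction(ranks[j]) for j in range(m))
    denom = m**2 * (n**3 - n) - m * ties

    def rec(j: int, col_sums: np.ndarray) -> None:
        nonlocal count, total
        if j == m:
            s = float(np.sum((col_sums - m * (n + 1) / 2.0) ** 2))
            w = 12.0 * s / denom
            total += 1
            count += w >= w_obs - 1e-12
            return
        for perm in perms:
            rec(j + 1, col_sums + ranks[j][list(perm)])

    rec(1, ranks[0].astype(float))
    return count / total


def screen_indicators(round_: ExpertRatingRound, rule: ScreeningRule) -> ScreeningResult:
    """Screen items by mean importance and coefficient of variation.

    An item is kept iff its mean rating >= ``min_mean_importance`` and its
    CV (sd/mean) <= ``max_cv``.  Full per-item statistics are returned so the
    screening decision can be audited.
    """
    means = round_.ratings.mean(axis=0)
    sds = round_.ratings.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means != 0, sds / means, np.inf)
    per_item = pd.DataFrame(
        {"mean": means, "sd": sds, "cv": cvs}, index=list(round_.item_ids)
    )
    keep = (means >= rule.min_mean_importance) & (cvs <= rule.max_cv)
    kept = [iid for iid, k in zip(round_.item_ids, keep) if k]
    dropped = [iid for iid, k in zip(round_.item_ids, keep) if not k]
    warning = "screening kept no items" if not kept else None
    return ScreeningResult(kept=kept, dropped=dropped, per_item=per_item, warning=warning)
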