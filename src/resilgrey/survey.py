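"""Respondent data: loading, validation, filtering and descriptive statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .scale import IndicatorTree

__all__ = [
    "ResponseTable",
    "ValidityRule",
    "FilterResult",
    "ResponseValidationError",
    "load_responses",
    "filter_valid",
    "recovery_rate",
]

#: covariate columns in response CSVs carry this prefix
META_PREFIX = "meta_"


class ResponseValidationError(ValueError):
    """Response file failed validation; carries per-row error records."""

    def __init__(self, message: str, row_errors: list[dict] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


@dataclass
class ResponseTable:
    """Respondent x third-level-indicator Likert ratings plus covariates.

    ``ratings`` is indexed by respondent id with one column per leaf
    indicator; ``covariates`` shares the index (gender, years-of-work band,
    job nature, major, certificates, exercise habit, training and drill
    participation, ...).
    """

    ratings: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    rating_min: float = 1.0
    rating_max: float = 5.0

    def __post_init__(self) -> None:
        if self.covariates.empty:
            self.covariates = pd.DataFrame(index=self.ratings.index)
        if not self.covariates.index.equals(self.ratings.index):
            raise ValueError("covariates index must match ratings index")
        vals = self.ratings.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < self.rating_min or finite.max() > self.rating_max):
            raise ResponseValidationError(
                f"ratings outside [{self.rating_min}, {self.rating_max}]"
            )

    @property
    def respondent_ids(self) -> list:
        return list(self.ratings.index)

    @property
    def leaf_ids(self) -> list[str]:
        return list(self.ratings.columns)

    @property
    def n_respondents(self) -> int:
        return len(self.ratings)

    def values(self) -> np.ndarray:
        return self.ratings.to_numpy(float)

    def subset(self, mask) -> "ResponseTable":
        return ResponseTable(
            self.ratings.loc[mask].copy(),
            self.covariates.loc[mask].copy(),
            self.rating_min,
            self.rating_max,
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.ratings.copy()
        for col in self.covariates.columns:
            df[META_PREFIX + str(col)] = self.covariates[col]
        df.index.name = "respondent_id"
        df.to_csv(path)


@dataclass
class ValidityRule:
    """Which records count as effectively recovered questionnaires.

    Defaults keep complete cases only (no missing ratings), do not penalise
    straight-lining, and do not require a consent flag — mirroring common
    survey-cleaning practice when the published exclusion criteria are
    unknown.
    """

    max_missing_fraction: float = 0.0
    straightline_max_run: int | None = None
    require_consent: bool = False
    consent_column: str = "consent"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")
        if self.straightline_max_run is not None and self.straightline_max_run < 1:
            raise ValueError("straightline_max_run must be >= 1")


@dataclass
class FilterResult:
    valid: ResponseTable
    excluded_count: int
    reasons: dict  # respondent id -> list of reason codes
    warning: str | None = None


def load_responses(path: str | Path, tree: IndicatorTree) -> ResponseTable:
    """Read a responses CSV and validate it against a tree's leaves.

    Expected layout: a ``respondent_id`` column, one column per leaf id, and
    covariates prefixed ``meta_``.  Unknown un-prefixed columns are kept as
    covariates with a warning attached to the error report; out-of-range
    ratings raise with per-row detail.
    """
    df = pd.read_csv(path)
    if "respondent_id" not in df.columns:
        raise ResponseValidationError("responses CSV lacks a 'respondent_id' column")
    df = df.set_index("respondent_id")
    df.columns = [str(c).strip() for c in df.columns]
    leaf_cols = [c for c in df.columns if c.lower() in set(tree.leaf_ids)]
    meta_cols = [c for c in df.columns if c.startswith(META_PREFIX)]
    unknown = [c for c in df.columns if c not in leaf_cols and c not in meta_cols]
    ratings = df[leaf_cols].copy()
    ratings.columns = [c.lower() for c in leaf_cols]
    ratings = ratings.apply(pd.to_numeric, errors="coerce")
    # reorder to the tree's canonical leaf order
    ratings = ratings[[lid for lid in tree.leaf_ids if lid in ratings.columns]]

    row_errors = []
    vals = df[leaf_cols].apply(pd.to_numeric, errors="coerce")
    bad = (vals < tree.rating_min) | (vals > tree.rating_max)
    for rid in df.index[bad.any(axis=1)]:
        cols = list(bad.columns[bad.loc[rid]])
        row_errors.append({"respondent_id": rid, "columns": cols, "error": "rating out of range"})
    if row_errors:
        raise ResponseValidationError(
            f"{len(row_errors)} row(s) contain out-of-range ratings", row_errors
        )

    covariates = df[meta_cols].copy()
    covariates.columns = [c[len(META_PREFIX):] for c in meta_cols]
    for c in unknown:
        covariates[c] = df[c]
    return ResponseTable(
        ratings, covariates, rating_min=tree.rating_min, rating_max=tree.rating_max
    )


def _longest_run(row: np.ndarray) -> int:
    best = run = 1
    for a, b in zip(row[:-1], row[1:]):
        run = run + 1 if (a == b and np.isfinite(a)) else 1
        best = max(best, run)
    return best


def filter_valid(table: ResponseTable, rule: ValidityRule | None = None) -> FilterResult:
    """Partition respondents into valid and excluded with per-row reason codes."""
    rule = rule or ValidityRule()
    reasons: dict = {}
    vals = table.values()
    missing_frac = np.mean(~np.isfinite(vals), axis=1)
    for rid, frac in zip(table.respondent_ids, missing_frac):
        if frac > rule.max_missing_fraction + 1e-12:
            reasons.setdefault(rid, []).append("missing_ratings")
    if rule.straightline_max_run is not None:
        for rid, row in zip(table.respondent_ids, vals):
            if _longest_run(row) > rule.straightline_max_run:
                reasons.setdefault(rid, []).append("straightlining")
    if rule.require_consent:
        if rule.consent_column not in table.covariates.columns:
            for rid in table.respondent_ids:
                reasons.setdefault(rid, []).append("no_consent_record")
        else:
            consent = table.covariates[rule.consent_column]
            for rid, ok in consent.items():
                if not bool(ok):
                    reasons.setdefault(rid, []).append("consent_refused")
    keep = [rid for rid in table.respondent_ids if rid not in reasons]
    valid = table.subset(keep)
    return FilterResult(
        valid=valid,
        excluded_count=table.n_respondents - len(keep),
        reasons=reasons,
        warning="no valid responses remain" if not keep else None,
    )


def recovery_rate(distributed: int, valid: int) -> float:
    """Effective recovery percentage, rounded half-up to one decimal.

    E.g. 347 valid out of 417 distributed gives 83.2.
    """
    if distributed <= 0:
        raise ValueError("distributed must be positive")
    if not 0 <= valid <= distributed:
        raise ValueError("valid count must lie in [0, distributed]")
    pct = Decimal(100 * valid) / Decimal(distributed)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
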