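"""Synthetic study data with known ground truth.

Three generators mirror the inputs of the evaluation pipeline, none of which
were published with the instrument they emulate:

* Delphi rating rounds — each expert's importance ratings mix a common
  item-quality vector with independent noise, so panel concordance is a dial;
* expert comparison-matrix panels — Saaty judgments quantised from a planted
  weight vector under multiplicative log-normal noise, so weight recovery can
  be measured against truth;
* Likert respondent cohorts — a latent resilience trait with planted
  covariate group effects, thresholded into ordinal ratings, with a planted
  number of invalid (blank) records so the cleaning funnel is testable.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ahm import ComparisonMatrix, quantize_saaty
from .delphi import ExpertRatingRound
from .scale import IndicatorTree
from .survey import ResponseTable

__all__ = [
    "CohortSpec",
    "PanelSpec",
    "DEFAULT_COVARIATES",
    "simulate_cohort",
    "simulate_panel",
    "simulate_delphi",
]

#: covariate vocabulary and marginal level fractions used when a cohort spec
#: does not override them; mirrors the demographics a community-health survey
#: of this kind records
DEFAULT_COVARIATES: dict[str, dict[str, float]] = {
    "gender": {"female": 0.7, "male": 0.3},
    "years_of_work": {"<5": 0.30, "5-10": 0.30, "11-15": 0.20, ">15": 0.20},
    "job_nature": {"clinical": 0.5, "public_health": 0.3, "administrative": 0.2},
    "major": {"clinical_medicine": 0.4, "public_health": 0.3, "nursing": 0.3},
    "certificates": {"yes": 0.6, "no": 0.4},
    "exercise_habit": {"stable": 0.3, "occasional": 0.4, "none": 0.3},
    "training": {"yes": 0.6, "no": 0.4},
    "drill": {"yes": 0.5, "no": 0.5},
}

#: standard-normal thresholds putting roughly (10, 20, 30, 25, 15)% of mass
#: in the five categories at zero latent trait
DEFAULT_CUTPOINTS = (-1.2816, -0.5244, 0.2533, 1.0364)


@dataclass
class CohortSpec:
    """Recipe for a synthetic respondent cohort.

    The latent resilience trait of respondent *i* is Normal with mean equal
    to the sum of that respondent's group effects and standard deviation
    ``trait_sd``; the latent response to item *j* adds a per-item intercept
    (sd ``item_intercept_sd``) and residual noise (sd ``item_noise_sd``) and
    is cut at ``likert_cutpoints`` into ordinal ratings.  ``group_effects``
    maps covariate name to ``{level: latent shift}``.  ``n_invalid`` records
    are blanked so downstream validity filtering removes exactly that many.
    """

    n_respondents: int = 347
    trait_sd: float = 1.0
    item_intercept_sd: float = 0.3
    item_noise_sd: float = 1.0
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    n_invalid: int = 0
    likert_cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    covariate_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_invalid > self.n_respondents:
            raise ValueError("n_invalid cannot exceed n_respondents")
        cps = tuple(self.likert_cutpoints)
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("likert_cutpoints must be strictly increasing")
        for fac in self.group_effects:
            if fac not in self.covariate_fractions:
                raise ValueError(f"group effect on unknown covariate {fac!r}")


@dataclass
class PanelSpec:
    """Recipe for a synthetic expert comparison-matrix panel.

    ``true_weights`` maps each sibling-group key (internal node id, or
    ``"root"`` for the level-1 group) to that group's planted child weights,
    each group summing to 1.  Each expert judges b_ij as the nearest Saaty
    value to (w_i / w_j) * exp(eps) with eps ~ Normal(0, judgment_noise_sd),
    reciprocity enforced by construction.
    """

    true_weights: dict[str, dict[str, float]]
    n_experts: int = 25
    judgment_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("need at least one expert")
        for group, weights in self.true_weights.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 5e-3:
                raise ValueError(f"true weights of group {group!r} sum to {total:.4f}")

    @classmethod
    def from_tree(cls, tree: IndicatorTree, n_experts: int = 25,
                  judgment_noise_sd: float = 0.1, seed: int = 0) -> "PanelSpec":
        """Plant the tree's own local weights as ground truth."""
        weights = {
            parent: {k.id: k.weight for k in kids}
            for parent, kids in tree.sibling_groups().items()
        }
        return cls(weights, n_experts, judgment_noise_sd, seed)


def simulate_panel(spec: PanelSpec) -> dict[str, list[ComparisonMatrix]]:
    """Per-sibling-group lists of expert Saaty matrices from planted weights."""
    rng = np.random.default_rng(spec.seed)
    out: dict[str, list[ComparisonMatrix]] = {}
    for group, weights in spec.true_weights.items():
        ids = list(weights)
        w = np.array([weights[i] for i in ids], dtype=float)
        n = len(ids)
        mats = []
        for _ in range(spec.n_experts):
            b = np.ones((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    eps = rng.normal(0.0, spec.judgment_noise_sd)
                    val = float(quantize_saaty(w[i] / w[j] * np.exp(eps)))
                    b[i, j] = val
                    b[j, i] = 1.0 / val
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mats.append(ComparisonMatrix(item_ids=list(ids), b=b))
        out[group] = mats
    return out


def simulate_cohort(spec: CohortSpec, tree: IndicatorTree) -> ResponseTable:
    """Likert respondent cohort on a tree's leaves, with planted effects."""
    rng = np.random.default_rng(spec.seed)
    n, leaves = spec.n_respondents, tree.leaf_ids
    n_items = len(leaves)

    covariates = {}
    for name, fractions in spec.covariate_fractions.items():
        levels = list(fractions)
        probs = np.array([fractions[lv] for lv in levels], dtype=float)
        probs = probs / probs.sum()
        covariates[name] = rng.choice(levels, size=n, p=probs)
    cov = pd.DataFrame(covariates, index=pd.RangeIndex(1, n + 1, name="respondent_id"))

    shift = np.zeros(n)
    for factor, effects in spec.group_effects.items():
        for level, delta in effects.items():
            shift += np.where(cov[factor].to_numpy() == level, float(delta), 0.0)

    trait = rng.normal(shift, spec.trait_sd)
    intercepts = rng.normal(0.0, spec.item_intercept_sd, size=n_items)
    latent = (
        trait[:, None]
        + intercepts[None, :]
        + rng.normal(0.0, spec.item_noise_sd, size=(n, n_items))
    )
    cutpoints = np.asarray(spec.likert_cutpoints, dtype=float)
    ratings = 1.0 + np.searchsorted(cutpoints, latent).astype(float)
    ratings_df = pd.DataFrame(ratings, index=cov.index, columns=leaves)

    if spec.n_invalid:
        invalid = rng.choice(n, size=spec.n_invalid, replace=False)
        ratings_df.iloc[invalid, :] = np.nan

    return ResponseTable(
        ratings_df, cov, rating_min=tree.rating_min, rating_max=tree.rating_max
    )


def simulate_delphi(
    n_experts: int, n_items: int, concordance: float, seed: int = 0, round: int = 1
) -> ExpertRatingRound:
    """One Delphi round with controllable inter-expert concordance.

    Each expert's latent item judgment mixes a common quality vector
    (weight ``concordance``) with independent noise (weight
    ``1 - concordance``), then is binned into a 1-5 importance rating by
    per-expert quintiles.  Concordance 1 makes every expert's ranking
    identical; concordance 0 makes them independent.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    quality = rng.normal(size=n_items)
    noise = rng.normal(size=(n_experts, n_items))
    latent = concordance * quality[None, :] + (1.0 - concordance) * noise
    ratings = np.empty_like(latent)
    for j in range(n_experts):
        cuts = np.quantile(latent[j], [0.2, 0.4, 0.6, 0.8])
        ratings[j] = 1 + np.searchsorted(cuts, latent[j])
    item_ids = [f"item{k + 1:03d}" for k in range(n_items)]
    return ExpertRatingRound(round=round, ratings=ratings, item_ids=item_ids)
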