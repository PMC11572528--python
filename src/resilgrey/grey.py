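"""Grey-system scoring of weighted questionnaire scales.

The scoring model treats each evaluation grade ("excellent", "good",
"medium", "poor") as a grey class with a piecewise-linear whitening weight
function over the rating axis.  Whitening values of the observed ratings are
pooled into grey evaluation coefficients per item, normalised into class-
membership (clustering-coefficient) vectors, propagated up the weighted
indicator tree, and collapsed into composite scores via grade values.  A
grey-relational scorer provides a second, per-respondent view: each
respondent's rating series is compared against the ideal reference series
through grey relational coefficients weighted by global leaf weights.

The user-facing entry point is :class:`GreyEvaluationModel`, whose ``fit()``
returns a :class:`GreyEvaluationResults` with the score report, per-
respondent scores and relational grades, group comparisons and a summary
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .scale import IndicatorTree, global_leaf_weights
from .survey import ResponseTable

__all__ = [
    "WhiteningFunction",
    "GreyScheme",
    "ScoreReport",
    "GreyEvaluationModel",
    "GreyEvaluationResults",
    "default_scheme",
    "whitening_value",
    "grey_coefficients",
    "cluster_tree",
    "grey_relational_score",
]

_FORMS = ("upper_limit", "lower_limit", "triangular", "moderate")


@dataclass(frozen=True)
class WhiteningFunction:
    """Piecewise-linear membership of a rating in one grey class.

    Forms (breakpoints strictly increasing on the rating axis):

    - ``upper_limit (a, b)``: 0 below ``a``, linear ramp, 1 at and above ``b``
    - ``lower_limit (a, b)``: 1 at and below ``a``, linear ramp, 0 at and
      above ``b``
    - ``triangular (a, b, c)``: 0 outside (a, c), peak 1 at ``b``
    - ``moderate (a, b)``: symmetric triangle peaking at ``b`` with support
      (a, 2b - a)
    """

    form: str
    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown whitening form {self.form!r}")
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in self.breakpoints))
        expected = {"upper_limit": 2, "lower_limit": 2, "triangular": 3, "moderate": 2}
        if len(self.breakpoints) != expected[self.form]:
            raise ValueError(
                f"{self.form} needs {expected[self.form]} breakpoints, "
                f"got {len(self.breakpoints)}"
            )
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.form == "upper_limit":
            a, b = self.breakpoints
            out = np.clip((x - a) / (b - a), 0.0, 1.0)
        elif self.form == "lower_limit":
            a, b = self.breakpoints
            out = np.clip((b - x) / (b - a), 0.0, 1.0)
        else:
            if self.form == "triangular":
                a, b, c = self.breakpoints
            else:  # moderate: symmetric about the peak
                a, b = self.breakpoints
                c = 2 * b - a
            up = (x - a) / (b - a)
            down = (c - x) / (c - b)
            out = np.clip(np.minimum(up, down), 0.0, 1.0)
        out = np.where(np.isfinite(x), out, np.nan)
        return float(out) if out.ndim == 0 else out


def whitening_value(f: WhiteningFunction, x: float, rating_min: float = 1.0,
                    rating_max: float = 5.0) -> float:
    """Evaluate one whitening function at a rating on the declared axis."""
    if not rating_min <= x <= rating_max:
        raise ValueError(f"rating {x} outside the axis [{rating_min}, {rating_max}]")
    return float(f(x))


@dataclass
class GreyScheme:
    """Ordered grey classes with whitening functions and grade values.

    ``grade_values`` attach a score to each class and must decrease strictly
    from the best class to the worst, so the composite score of a node is
    its class-membership vector dotted with the grade values.
    """

    classes: tuple[str, ...]
    functions: dict[str, WhiteningFunction]
    grade_values: dict[str, float]

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        missing = [c for c in self.classes if c not in self.functions]
        if missing:
            raise ValueError(f"no whitening function for classes {missing}")
        gv = [self.grade_values[c] for c in self.classes]
        if any(b >= a for a, b in zip(gv, gv[1:])):
            raise ValueError("grade values must strictly decrease from best to worst")

    @property
    def grades(self) -> np.ndarray:
        return np.array([self.grade_values[c] for c in self.classes])

    def memberships(self, ratings: np.ndarray) -> np.ndarray:
        """Whitening values, shape ``ratings.shape + (n_classes,)``."""
        return np.stack([self.functions[c](ratings) for c in self.classes], axis=-1)

    @classmethod
    def from_yaml(cls, path) -> "GreyScheme":
        doc = yaml.safe_load(open(path).read()) if isinstance(path, (str,)) else yaml.safe_load(path.read_text())
        classes, functions, grades = [], {}, {}
        for entry in doc["classes"]:
            name = entry["name"]
            classes.append(name)
            functions[name] = WhiteningFunction(entry["form"], tuple(entry["breakpoints"]))
            grades[name] = float(entry["grade_value"])
        return cls(tuple(classes), functions, grades)

    def to_yaml_dict(self) -> dict:
        return {
            "classes": [
                {
                    "name": c,
                    "form": self.functions[c].form,
                    "breakpoints": list(self.functions[c].breakpoints),
                    "grade_value": self.grade_values[c],
                }
                for c in self.classes
            ]
        }


def default_scheme() -> GreyScheme:
    """Four grey classes tiling a 1-5 Likert axis.

    The exact turning points of the published instrument are unknown; this
    reconstruction tiles the axis so that every admissible rating has
    positive total membership, adjacent classes overlap linearly, and the
    extreme ratings belong purely to the extreme classes (a rating of 5 is
    wholly "excellent", a rating of 1 or 2 wholly "poor").
    """
    return GreyScheme(
        classes=("excellent", "good", "medium", "poor"),
        functions={
            "excellent": WhiteningFunction("upper_limit", (4, 5)),
            "good": WhiteningFunction("triangular", (3, 4, 5)),
            "medium": WhiteningFunction("triangular", (2, 3, 4)),
            "poor": WhiteningFunction("lower_limit", (2, 3)),
        },
        grade_values={"excellent": 1.0, "good": 0.8, "medium": 0.6, "poor": 0.4},
    )


@dataclass
class ScoreReport:
    """Clustering coefficients, composite scores and respondent summaries.

    ``nodes`` is indexed by node id (plus ``overall``) with the pooled
    class-membership vector, the pooled composite score, and the median /
    interquartile range of the per-respondent composite scores.
    ``respondent_scores`` holds the per-respondent composite score at every
    node (respondents x nodes).
    """

    nodes: pd.DataFrame
    respondent_scores: pd.DataFrame
    classes: tuple[str, ...]
    degenerate_leaves: list[str] = field(default_factory=list)

    def composite(self, node_id: str = "overall") -> float:
        return float(self.nodes.loc[node_id, "composite"])

    def membership(self, node_id: str = "overall") -> np.ndarray:
        return self.nodes.loc[node_id, [f"r_{c}" for c in self.classes]].to_numpy(float)


def grey_coefficients(
    responses: ResponseTable, scheme: GreyScheme, leaf: str
) -> dict[str, np.ndarray | bool]:
    """Grey evaluation coefficients for one leaf indicator.

    ``n_e`` sums each class's whitening values over respondents; the grey
    evaluation weights ``r_e = n_e / sum(n)`` form the leaf's class-
    membership vector.  A leaf where every whitening value vanishes is
    flagged degenerate instead of raising.
    """
    leaf = leaf.lower()
    if leaf not in responses.ratings.columns:
        raise KeyError(f"leaf {leaf!r} not present in the response table")
    x = responses.ratings[leaf].to_numpy(float)
    memb = scheme.memberships(x)  # (R, C), NaN rows for missing ratings
    n_e = np.nansum(memb, axis=0)
    total = n_e.sum()
    degenerate = bool(total <= 0)
    r_e = n_e / total if not degenerate else np.full(len(scheme.classes), np.nan)
    return {"n_e": n_e, "r_e": r_e, "N": total, "degenerate": degenerate}


def _node_membership(
    tree: IndicatorTree, node_id: str | None, leaf_r: dict[str, np.ndarray]
) -> np.ndarray:
    """Weighted recursion: a node's membership is the renormalised local-
    weight mixture of its children's memberships."""
    kids = tree.children(node_id)
    if not kids:  # leaf
        return leaf_r[node_id]
    acc = None
    for kid in kids:
        r = _node_membership(tree, kid.id, leaf_r)
        contrib = kid.weight * r
        acc = contrib if acc is None else acc + contrib
    # NaN-aware renormalisation along the class axis (last axis)
    total = np.nansum(acc, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, acc / total, np.nan)


def cluster_tree(
    responses: ResponseTable, tree: IndicatorTree, scheme: GreyScheme | None = None
) -> ScoreReport:
    """Fixed-weight grey clustering through the indicator tree.

    Two parallel aggregations are run with the same recursion:

    * pooled — per-leaf grey evaluation weights over the whole cohort,
      mixed upward by local weights and renormalised; composite = membership
      dot grade values;
    * per-respondent — each respondent's own whitening memberships,
      normalised within each leaf, aggregated identically; the resulting
      per-respondent composites yield each node's median and interquartile
      range.
    """
    scheme = scheme or default_scheme()
    missing = [lid for lid in tree.leaf_ids if lid not in responses.ratings.columns]
    if missing:
        raise ValueError(f"response table lacks leaf columns: {missing}")
    if responses.n_respondents < 1:
        raise ValueError("need at least one respondent")

    grades = scheme.grades
    classes = scheme.classes
    ratings = responses.ratings[tree.leaf_ids].to_numpy(float)  # (R, L)
    memb = scheme.memberships(ratings)  # (R, L, C)

    # pooled coefficients per leaf
    pooled_n = np.nansum(memb, axis=0)  # (L, C)
    pooled_tot = pooled_n.sum(axis=1, keepdims=True)
    degenerate = [
        lid for lid, t in zip(tree.leaf_ids, pooled_tot[:, 0]) if not t > 0
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_r = np.where(pooled_tot > 0, pooled_n / pooled_tot, np.nan)

    # per-respondent memberships normalised within each leaf
    resp_tot = np.nansum(memb, axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        resp_r = np.where(resp_tot > 0, memb / resp_tot, np.nan)  # (R, L, C)

    leaf_pooled = {lid: pooled_r[i] for i, lid in enumerate(tree.leaf_ids)}
    leaf_resp = {lid: resp_r[:, i, :] for i, lid in enumerate(tree.leaf_ids)}

    node_ids = ["overall"] + [n.id for n in tree.nodes]
    rows = []
    resp_cols = {}
    for node_id in node_ids:
        key = None if node_id == "overall" else node_id
        level = 0 if node_id == "overall" else tree[node_id].level
        r_pool = _node_membership(tree, key, leaf_pooled)
        r_resp = _node_membership(tree, key, leaf_resp)  # (R, C)
        comp_pool = float(np.dot(r_pool, grades)) if np.all(np.isfinite(r_pool)) else np.nan
        comp_resp = r_resp @ grades  # (R,)
        resp_cols[node_id] = comp_resp
        q1, med, q3 = np.nanpercentile(comp_resp, [25, 50, 75])
        row = {"node_id": node_id, "level": level, "composite": comp_pool,
               "median": med, "iqr": q3 - q1, "q1": q1, "q3": q3}
        for c, rv in zip(classes, r_pool):
            row[f"r_{c}"] = rv
        rows.append(row)

    nodes = pd.DataFrame(rows).set_index("node_id")
    respondent_scores = pd.DataFrame(resp_cols, index=responses.ratings.index)
    return ScoreReport(
        nodes=nodes,
        respondent_scores=respondent_scores,
        classes=classes,
        degenerate_leaves=degenerate,
    )


def grey_relational_score(
    responses: ResponseTable, tree: IndicatorTree, rho: float = 0.5
) -> pd.Series:
    """Grey relational grade of each respondent against the reference series.

    The reference series takes each leaf's maximal observed rating; the
    relational coefficient for respondent i on leaf k is
    ``(dmin + rho * dmax) / (d_ik + rho * dmax)`` with ``d_ik`` the absolute
    deviation from the reference and ``dmin``/``dmax`` the global extrema
    over the whole table.  The relational grade averages the coefficients
    with normalised global leaf weights; a constant table (dmax = 0) gives
    every respondent grade 1.
    """
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    ratings = responses.ratings[tree.leaf_ids].to_numpy(float)
    ref = np.nanmax(ratings, axis=0)  # (L,)
    delta = np.abs(ref[None, :] - ratings)  # (R, L)
    dmax = float(np.nanmax(delta))
    if dmax == 0:
        grades = np.ones(ratings.shape[0])
    else:
        dmin = float(np.nanmin(delta))
        gamma = (dmin + rho * dmax) / (delta + rho * dmax)
        gw = global_leaf_weights(tree)
        w = np.array([gw[lid] for lid in tree.leaf_ids])
        w = w / w.sum()
        grades = gamma @ w
    return pd.Series(grades, index=responses.ratings.index, name="relational_grade")


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------


class GreyEvaluationModel:
    """Grey whitening-weight evaluation of a cohort on a weighted scale.

    Parameters
    ----------
    responses
        Respondent ratings and covariates (see :class:`ResponseTable`).
    tree
        The weighted indicator hierarchy whose leaves the respondents rated.
    scheme
        Grey classes with whitening functions and grade values; the default
        reconstructs a four-class excellent/good/medium/poor scheme on a
        1-5 axis.
    rho
        Distinguishing coefficient of the grey relational scorer, in (0, 1].
    """

    def __init__(
        self,
        responses: ResponseTable,
        tree: IndicatorTree,
        scheme: GreyScheme | None = None,
        rho: float = 0.5,
    ):
        self.responses = responses
        self.tree = tree
        self.scheme = scheme or default_scheme()
        self.rho = float(rho)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        tree: IndicatorTree,
        scheme: GreyScheme | None = None,
        rho: float = 0.5,
    ) -> "GreyEvaluationModel":
        """Build from a flat frame with leaf columns and ``meta_`` covariates."""
        from .survey import META_PREFIX

        leaf_cols = [c for c in df.columns if str(c).lower() in set(tree.leaf_ids)]
        meta_cols = [c for c in df.columns if str(c).startswith(META_PREFIX)]
        ratings = df[leaf_cols].copy()
        ratings.columns = [str(c).lower() for c in leaf_cols]
        cov = df[meta_cols].copy()
        cov.columns = [str(c)[len(META_PREFIX):] for c in meta_cols]
        table = ResponseTable(ratings, cov, tree.rating_min, tree.rating_max)
        return cls(table, tree, scheme, rho)

    def fit(self) -> "GreyEvaluationResults":
        report = cluster_tree(self.responses, self.tree, self.scheme)
        relational = grey_relational_score(self.responses, self.tree, self.rho)
        return GreyEvaluationResults(self, report, relational)


class GreyEvaluationResults:
    """Fitted grey evaluation: scores, memberships and summaries."""

    def __init__(self, model: GreyEvaluationModel, report: ScoreReport,
                 relational_grades: pd.Series):
        self.model = model
        self.report = report
        self.relational_grades = relational_grades

    @property
    def nodes(self) -> pd.DataFrame:
        return self.report.nodes

    @property
    def respondent_scores(self) -> pd.DataFrame:
        return self.report.respondent_scores

    @property
    def overall_score(self) -> float:
        return self.report.composite("overall")

    def compare_by(self, factor: str, node: str = "overall", **kwargs):
        """Rank-based comparison of a node's respondent scores across a
        covariate's groups (see :func:`resilgrey.compare.compare_by_factor`)."""
        from .compare import compare_by_factor

        return compare_by_factor(
            self.respondent_scores[node], self.model.responses, factor, **kwargs
        )

    def summary(self, levels: tuple[int, ...] = (0, 1, 2)) -> str:
        """Human-readable score table down to the requested levels."""
        classes = self.report.classes
        nodes = self.nodes[self.nodes["level"].isin(levels)]
        lines = [
            "Grey whitening-weight evaluation",
            "=" * 72,
            f"respondents: {self.model.responses.n_respondents}    "
            f"leaves: {len(self.model.tree.leaf_ids)}    "
            f"classes: {', '.join(classes)}",
            f"grade values: "
            + ", ".join(f"{c}={self.model.scheme.grade_values[c]:g}" for c in classes),
            "-" * 72,
            f"{'node':<10}{'level':>6}{'composite':>11}{'median':>9}{'IQR':>8}  "
            + " ".join(f"{('r_' + c)[:6]:>7}" for c in classes),
        ]
        for node_id, row in nodes.iterrows():
            lines.append(
                f"{node_id:<10}{int(row['level']):>6}{row['composite']:>11.4f}"
                f"{row['median']:>9.4f}{row['iqr']:>8.4f}  "
                + " ".join(f"{row[f'r_{c}']:>7.4f}" for c in classes)
            )
        lines.append("-" * 72)
        lines.append(
            f"mean grey relational grade (rho={self.model.rho:g}): "
            f"{float(self.relational_grades.mean()):.4f}"
        )
        if self.report.degenerate_leaves:
            lines.append(f"degenerate leaves: {self.report.degenerate_leaves}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.nodes.copy()
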