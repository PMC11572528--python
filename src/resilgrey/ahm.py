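"""Indicator weighting from pairwise comparisons.

Weights are derived from Saaty 1-9 pairwise comparison matrices via the
attribute hierarchy model (AHM): the comparison matrix is converted to an
attribute-measure matrix whose off-diagonal pairs sum to 1, and weights are
scaled row sums — no eigenvector and no consistency requirement.  The
classical AHP principal-eigenvector weights with Saaty's consistency ratio
are provided as a diagnostic cross-check, and expert panels are pooled by
the element-wise geometric mean of their matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .scale import IndicatorTree

__all__ = [
    "ComparisonMatrix",
    "AttributeMeasureMatrix",
    "AhpResult",
    "SAATY_RI",
    "to_attribute_measure",
    "ahm_weights",
    "ahp_eigen_weights",
    "aggregate_experts",
    "weight_tree",
]

#: Saaty's random consistency index for n = 1..15.
SAATY_RI = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
    9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56, 14: 1.57, 15: 1.59,
}

_SAATY_VALUES = np.array(
    [1 / 9, 1 / 8, 1 / 7, 1 / 6, 1 / 5, 1 / 4, 1 / 3, 1 / 2,
     1, 2, 3, 4, 5, 6, 7, 8, 9]
)


@dataclass
class ComparisonMatrix:
    """One judge's Saaty-scale pairwise comparisons over a sibling group."""

    item_ids: list[str]
    b: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.item_ids)
        if self.b.shape != (n, n):
            raise ValueError(f"matrix shape {self.b.shape} != ({n}, {n})")
        if np.any(self.b <= 0):
            raise ValueError("comparison matrix entries must be positive")
        if not np.allclose(np.diag(self.b), 1.0, atol=1e-9):
            raise ValueError("comparison matrix diagonal must be 1")
        if not np.allclose(self.b * self.b.T, 1.0, atol=1e-9):
            raise ValueError("comparison matrix must be reciprocal: b_ji = 1/b_ij")
        off = self.b[~np.eye(n, dtype=bool)]
        big = np.maximum(off, 1.0 / off)
        if off.size and not np.all(
            np.isclose(big[:, None], np.arange(1, 10)[None, :], atol=1e-9).any(axis=1)
        ):
            warnings.warn(
                "comparison matrix contains non-Saaty entries (expected for "
                "geometric-mean aggregates)",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return len(self.item_ids)

    @classmethod
    def from_weights(cls, item_ids: list[str], weights) -> "ComparisonMatrix":
        """Perfectly consistent matrix b_ij = w_i / w_j (no Saaty rounding)."""
        w = np.asarray(weights, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(item_ids, np.outer(w, 1.0 / w))


@dataclass
class AttributeMeasureMatrix:
    """AHM relative-attribute measures: u_ii = 0, u_ij + u_ji = 1 off-diagonal."""

    item_ids: list[str]
    u: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        n = len(self.item_ids)
        if self.u.shape != (n, n):
            raise ValueError("attribute-measure matrix shape mismatch")
        if not np.allclose(np.diag(self.u), 0.0, atol=1e-12):
            raise ValueError("attribute-measure diagonal must be 0")
        pair = self.u + self.u.T
        if n > 1 and not np.allclose(pair[~np.eye(n, dtype=bool)], 1.0, atol=1e-9):
            raise ValueError("u_ij + u_ji must equal 1 off-diagonal")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def n(self) -> int:
        return len(self.item_ids)


@dataclass
class AhpResult:
    weights: np.ndarray
    lambda_max: float
    CI: float
    CR: float


def to_attribute_measure(m: ComparisonMatrix, beta: float = 2.0) -> AttributeMeasureMatrix:
    """Convert a comparison matrix to AHM attribute measures.

    For b_ij = k > 1: u_ij = beta*k / (beta*k + 1) and u_ji = 1 / (beta*k + 1);
    for b_ij = 1 (i != j): u_ij = u_ji = 1/2.  Entries below 1 are handled
    through their reciprocal, and non-integer k > 1 (from aggregation) by the
    same formula.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    n = m.n
    u = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            k = m.b[i, j]
            if np.isclose(k, 1.0):
                u[i, j] = u[j, i] = 0.5
            elif k > 1:
                u[i, j] = beta * k / (beta * k + 1)
                u[j, i] = 1.0 / (beta * k + 1)
            else:
                k = 1.0 / k
                u[j, i] = beta * k / (beta * k + 1)
                u[i, j] = 1.0 / (beta * k + 1)
    return AttributeMeasureMatrix(item_ids=list(m.item_ids), u=u, beta=beta)


def ahm_weights(u: AttributeMeasureMatrix) -> np.ndarray:
    """AHM weights: w_i = 2 / (n (n - 1)) * sum_j u_ij.

    The pair-sum identity u_ij + u_ji = 1 forces sum(w) = 1 exactly (up to
    floating round-off), with every w_i >= 0.
    """
    n = u.n
    if n < 2:
        raise ValueError("AHM weights need at least 2 items")
    return 2.0 / (n * (n - 1)) * u.u.sum(axis=1)


def ahp_eigen_weights(
    m: ComparisonMatrix, max_iter: int = 10_000, tol: float = 1e-12
) -> AhpResult:
    """Classical AHP: principal-eigenvector weights plus consistency ratio.

    The principal eigenpair is found by power iteration (a positive matrix
    has a simple dominant eigenvalue, so this converges); CI = (lambda_max -
    n)/(n - 1) and CR = CI / RI(n), with CR := 0 for n <= 2.
    """
    n = m.n
    if n > max(SAATY_RI):
        raise ValueError(f"consistency ratio undefined beyond n = {max(SAATY_RI)}")
    v = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(max_iter):
        nv = m.b @ v
        lam = nv.sum()  # since v sums to 1, Rayleigh-like estimate
        nv /= nv.sum()
        if np.abs(nv - v).max() < tol:
            v = nv
            break
        v = nv
    else:
        raise RuntimeError(
            f"power iteration did not converge after {max_iter} iterations "
            f"(residual {np.abs(m.b @ v / (m.b @ v).sum() - v).max():.2e})"
        )
    lambda_max = float((m.b @ v).sum())
    ci = (lambda_max - n) / (n - 1) if n > 1 else 0.0
    cr = 0.0 if n <= 2 else ci / SAATY_RI[n]
    return AhpResult(weights=v, lambda_max=lambda_max, CI=ci, CR=cr)


def aggregate_experts(matrices: list[ComparisonMatrix]) -> ComparisonMatrix:
    """Pool experts by the element-wise geometric mean.

    The geometric mean of reciprocal matrices is reciprocal, so the pooled
    matrix is re-validated as a ComparisonMatrix (its entries generally fall
    off the integer Saaty grid).
    """
    if not matrices:
        raise ValueError("no matrices to aggregate")
    ids = matrices[0].item_ids
    for m in matrices[1:]:
        if m.item_ids != ids:
            raise ValueError(f"item sets differ: {ids} vs {m.item_ids}")
    logs = np.mean([np.log(m.b) for m in matrices], axis=0)
    # antisymmetrise the log matrix so reciprocity is exact despite float drift
    logs = (logs - logs.T) / 2.0
    b = np.exp(logs)
    np.fill_diagonal(b, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ComparisonMatrix(item_ids=list(ids), b=b)


def aggregate_expert_weights(
    matrices: list[ComparisonMatrix], beta: float = 2.0
) -> np.ndarray:
    """Alternative pooling: arithmetic mean of per-expert AHM weights."""
    ws = [ahm_weights(to_attribute_measure(m, beta)) for m in matrices]
    w = np.mean(ws, axis=0)
    return w / w.sum()


def weight_tree(
    tree: IndicatorTree,
    matrices: dict[str, list[ComparisonMatrix]],
    beta: float = 2.0,
) -> IndicatorTree:
    """Re-weight a tree from per-sibling-group expert comparison matrices.

    ``matrices`` maps each internal node id (and ``"root"`` for the level-1
    group) to that group's list of expert matrices.  Matrices are pooled by
    geometric mean, converted to attribute measures and weighted by AHM;
    single-child groups get weight 1.  Sibling sums are exactly 1 by the AHM
    pair-sum identity.
    """
    groups = tree.sibling_groups()
    new_weights: dict[str, float] = {}
    for parent_id, kids in groups.items():
        kid_ids = [k.id for k in kids]
        if parent_id not in matrices:
            raise ValueError(f"no comparison matrices for sibling group {parent_id!r}")
        group_mats = matrices[parent_id]
        for m in group_mats:
            if sorted(m.item_ids) != sorted(kid_ids):
                raise ValueError(
                    f"matrix items {m.item_ids} do not match children of "
                    f"{parent_id!r}: {kid_ids}"
                )
        if len(kid_ids) == 1:
            new_weights[kid_ids[0]] = 1.0
            continue
        pooled = aggregate_experts(group_mats)
        w = ahm_weights(to_attribute_measure(pooled, beta))
        for item_id, wi in zip(pooled.item_ids, w):
            new_weights[item_id] = float(wi)
    extra = set(matrices) - set(groups)
    if extra:
        raise ValueError(f"matrices supplied for unknown sibling groups: {sorted(extra)}")
    return tree.with_weights(new_weights)


def quantize_saaty(ratio: float | np.ndarray) -> np.ndarray:
    """Nearest Saaty-scale value (1/9..9) on the log scale."""
    ratio = np.asarray(ratio, dtype=float)
    idx = np.abs(np.log(ratio)[..., None] - np.log(_SAATY_VALUES)).argmin(axis=-1)
    return _SAATY_VALUES[idx]
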