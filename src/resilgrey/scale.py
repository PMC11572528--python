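"""Weighted three-level indicator hierarchies.

An evaluation scale is a tree of indicators: first-level domains, second-level
contents, third-level questionnaire items (the leaves respondents actually
rate).  Every node carries a *local* weight — its share within its sibling
group — and the product of local weights down a root path gives the *global*
weight of a leaf, which is what score aggregation uses.

Scale definitions are read from a hierarchical YAML dialect or an equivalent
flat CSV (``id,parent_id,level,weight,text``).  The packaged emergency-
resilience scale for grassroots medical workers (3 domains, 13 contents,
46 items) ships in both dialects.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "IndicatorNode",
    "IndicatorTree",
    "ScaleValidationError",
    "load_scale",
    "load_packaged_scale",
    "global_leaf_weights",
]

#: printed weights are rounded to 3 decimals, so sibling groups may sum to
#: 0.999 or 1.001
SIBLING_SUM_TOL = 5e-3
GLOBAL_SUM_TOL = 1e-2


class ScaleValidationError(ValueError):
    """A scale definition violated a structural invariant.

    Carries the offending node or sibling-group id so errors can be traced
    back to the definition file.
    """

    def __init__(self, message: str, node_id: str | None = None):
        super().__init__(message)
        self.node_id = node_id


@dataclass
class IndicatorNode:
    """One indicator: a domain (level 1), content (level 2) or item (level 3)."""

    id: str
    level: int
    parent_id: str | None
    text: str
    weight: float

    def __post_init__(self) -> None:
        self.id = str(self.id).strip().lower()
        if self.parent_id is not None:
            self.parent_id = str(self.parent_id).strip().lower() or None
        if self.level not in (1, 2, 3):
            raise ScaleValidationError(
                f"node {self.id!r}: level must be 1, 2 or 3, got {self.level}",
                self.id,
            )
        if (self.parent_id is None) != (self.level == 1):
            raise ScaleValidationError(
                f"node {self.id!r}: level-{self.level} node must "
                f"{'not ' if self.level == 1 else ''}have a parent",
                self.id,
            )
        if not 0.0 <= self.weight <= 1.0:
            raise ScaleValidationError(
                f"node {self.id!r}: weight {self.weight} outside [0, 1]", self.id
            )


@dataclass
class IndicatorTree:
    """A validated three-level weighted indicator hierarchy."""

    nodes: list[IndicatorNode]
    rating_min: float = 1.0
    rating_max: float = 5.0
    name: str = ""
    _index: dict[str, IndicatorNode] = field(init=False, repr=False)
    _children: dict[str | None, list[IndicatorNode]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        self._children = {}
        for node in self.nodes:
            if node.id in self._index:
                raise ScaleValidationError(f"duplicate indicator id {node.id!r}", node.id)
            self._index[node.id] = node
        for node in self.nodes:
            self._children.setdefault(node.parent_id, []).append(node)
        self._validate()

    # -- access ---------------------------------------------------------

    def __getitem__(self, node_id: str) -> IndicatorNode:
        return self._index[str(node_id).lower()]

    def __contains__(self, node_id: str) -> bool:
        return str(node_id).lower() in self._index

    def children(self, node_id: str | None) -> list[IndicatorNode]:
        """Children of a node; ``None`` returns the level-1 roots."""
        key = None if node_id is None else str(node_id).lower()
        return list(self._children.get(key, []))

    def level_nodes(self, level: int) -> list[IndicatorNode]:
        return [n for n in self.nodes if n.level == level]

    @property
    def leaves(self) -> list[IndicatorNode]:
        return self.level_nodes(3)

    @property
    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves]

    def internal_ids(self) -> list[str]:
        """Ids of nodes that have children (levels 1 and 2)."""
        return [n.id for n in self.nodes if n.level < 3]

    def root_path(self, leaf_id: str) -> list[IndicatorNode]:
        node = self[leaf_id]
        path = [node]
        while node.parent_id is not None:
            node = self[node.parent_id]
            path.append(node)
        return path[::-1]

    # -- validation -----------------------------------------------------

    def _validate(self) -> None:
        for node in self.nodes:
            if node.parent_id is not None:
                parent = self._index.get(node.parent_id)
                if parent is None:
                    raise ScaleValidationError(
                        f"node {node.id!r}: missing parent {node.parent_id!r}",
                        node.id,
                    )
                if parent.level != node.level - 1:
                    raise ScaleValidationError(
                        f"node {node.id!r} (level {node.level}) has parent "
                        f"{parent.id!r} of level {parent.level}; expected level "
                        f"{node.level - 1}",
                        node.id,
                    )
        for level in (1, 2, 3):
            if not self.level_nodes(level):
                raise ScaleValidationError(f"tree has no level-{level} nodes")
        for node in self.level_nodes(1) + self.level_nodes(2):
            if not self._children.get(node.id):
                raise ScaleValidationError(
                    f"internal node {node.id!r} has no children", node.id
                )
        for group_parent, kids in self.sibling_groups().items():
            total = sum(k.weight for k in kids)
            if abs(total - 1.0) > SIBLING_SUM_TOL:
                raise ScaleValidationError(
                    f"weights of children of {group_parent!r} sum to "
                    f"{total:.4f}, not 1 ± {SIBLING_SUM_TOL}",
                    group_parent,
                )
        total = sum(global_leaf_weights(self).values())
        if abs(total - 1.0) > GLOBAL_SUM_TOL:
            raise ScaleValidationError(
                f"global leaf weights sum to {total:.4f}, not 1 ± {GLOBAL_SUM_TOL}"
            )

    def sibling_groups(self) -> dict[str, list[IndicatorNode]]:
        """All weight groups, keyed by parent id ('root' for the level-1 trio)."""
        groups: dict[str, list[IndicatorNode]] = {"root": self.children(None)}
        for node_id in self.internal_ids():
            groups[node_id] = self.children(node_id)
        return groups

    # -- serialisation --------------------------------------------------

    def with_weights(self, weights: dict[str, float]) -> "IndicatorTree":
        """Copy of the tree with some local weights replaced."""
        nodes = [
            IndicatorNode(
                n.id, n.level, n.parent_id, n.text, float(weights.get(n.id, n.weight))
            )
            for n in self.nodes
        ]
        return IndicatorTree(nodes, self.rating_min, self.rating_max, self.name)

    def to_yaml(self, path: str | Path | None = None) -> str:
        def node_dict(n: IndicatorNode) -> dict:
            d: dict = {"id": n.id, "text": n.text, "weight": n.weight}
            kids = self.children(n.id)
            if kids:
                d["children"] = [node_dict(k) for k in kids]
            return d

        doc = {
            "name": self.name,
            "rating_scale": {"min": self.rating_min, "max": self.rating_max},
            "indicators": [node_dict(n) for n in self.children(None)],
        }
        text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["id", "parent_id", "level", "weight", "text"])
        for n in self.nodes:
            writer.writerow([n.id, n.parent_id or "", n.level, n.weight, n.text])
        if path is not None:
            Path(path).write_text(buf.getvalue())
        return buf.getvalue()


def _nodes_from_yaml_doc(doc: dict) -> tuple[list[IndicatorNode], dict]:
    nodes: list[IndicatorNode] = []

    def walk(entry: dict, level: int, parent_id: str | None) -> None:
        try:
            node = IndicatorNode(
                id=entry["id"],
                level=level,
                parent_id=parent_id,
                text=str(entry.get("text", "")),
                weight=float(entry["weight"]),
            )
        except KeyError as exc:
            raise ScaleValidationError(
                f"indicator entry missing field {exc} (parent {parent_id!r})",
                parent_id,
            ) from exc
        nodes.append(node)
        for child in entry.get("children", []) or []:
            walk(child, level + 1, node.id)

    for top in doc.get("indicators", []):
        walk(top, 1, None)
    return nodes, doc


def load_scale(path: str | Path) -> IndicatorTree:
    """Load and validate a scale definition (YAML or CSV, by extension/content).

    Raises :class:`ScaleValidationError` naming the offending node or sibling
    group on any structural violation (missing parent, duplicate id, weight
    out of range, sibling-sum violation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".csv" or text.lstrip().startswith("id,"):
        return _load_csv(text)
    return _load_yaml(text)


def _load_yaml(text: str) -> IndicatorTree:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "indicators" not in doc:
        raise ScaleValidationError("scale YAML must contain an 'indicators' list")
    nodes, doc = _nodes_from_yaml_doc(doc)
    scale = doc.get("rating_scale", {}) or {}
    return IndicatorTree(
        nodes,
        rating_min=float(scale.get("min", 1)),
        rating_max=float(scale.get("max", 5)),
        name=str(doc.get("name", "")),
    )


def _load_csv(text: str) -> IndicatorTree:
    reader = csv.DictReader(io.StringIO(text))
    nodes = []
    for row in reader:
        nodes.append(
            IndicatorNode(
                id=row["id"],
                level=int(row["level"]),
                parent_id=row.get("parent_id") or None,
                text=row.get("text", ""),
                weight=float(row["weight"]),
            )
        )
    return IndicatorTree(nodes)


def load_packaged_scale() -> IndicatorTree:
    """The packaged grassroots-medical-worker emergency-resilience scale."""
    ref = resources.files("resilgrey.data") / "scale_table.yaml"
    return _load_yaml(ref.read_text())


def global_leaf_weights(tree: IndicatorTree) -> dict[str, float]:
    """Map each leaf to the product of local weights along its root path.

    Sums to 1 up to the rounding of the printed local weights.
    """
    out: dict[str, float] = {}
    for leaf in tree.leaves:
        w = 1.0
        for node in tree.root_path(leaf.id):
            w *= node.weight
        out[leaf.id] = w
    return out
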