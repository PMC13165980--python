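"""Label taxonomy for hierarchical binary classification.

A multi-class labelling problem over ``K`` leaf classes is organised as a
two-level tree: a root that splits the leaves into named groups (here the
dermatological default: Benign vs Malignant), and, within each group, a
chain of one-vs-rest "peel" decisions that isolate one class at a time
until only a pair remains.  Every decision in the assembled tree is a
binary classification task, so a single ``K``-way problem decomposes into
a small set of easier two-way problems (local classifier per node).

The shipped default covers the six lesion classes
ACK / NEV / SEK (benign) and MEL / BCC / SCC (malignant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ClassLabel",
    "LabelTaxonomy",
    "DecisionNode",
    "BinaryTask",
    "TaxonomyError",
    "default_taxonomy",
    "candidate_tasks",
    "decision_nodes",
    "enumerate_training_runs",
]

#: Canonical order of the task stages, root split first.
STAGES = ("root", "group_peel", "residual_pair")


class TaxonomyError(ValueError):
    """Raised for malformed taxonomies, peel orders or task lists."""


@dataclass(frozen=True)
class ClassLabel:
    """A leaf class: a short unique code plus a human-readable name."""

    code: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.code:
            raise TaxonomyError("class code must be a nonempty string")


@dataclass(frozen=True)
class BinaryTask:
    """One binary classification task: ``positive_set`` vs ``negative_set``.

    ``stage`` records where the task sits in the decomposition:
    ``root`` (group A vs group B), ``group_peel`` (one class vs the rest of
    its group) or ``residual_pair`` (the two classes left after a peel).
    """

    task_name: str
    positive_set: frozenset
    negative_set: frozenset
    stage: str

    def __post_init__(self) -> None:
        _check_sets(self.positive_set, self.negative_set)
        if self.stage not in STAGES:
            raise TaxonomyError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class DecisionNode:
    """A node of the assembled classifier tree.

    ``parent_branch`` is ``(parent_node_id, outcome)`` with outcome
    ``"positive"`` or ``"negative"``; it is ``None`` for the root.
    """

    node_id: str
    positive_set: frozenset
    negative_set: frozenset
    parent_branch: tuple | None = None

    def __post_init__(self) -> None:
        _check_sets(self.positive_set, self.negative_set)

    @property
    def reachable(self) -> frozenset:
        return self.positive_set | self.negative_set


def _check_sets(pos: frozenset, neg: frozenset) -> None:
    if not pos or not neg:
        raise TaxonomyError("positive and negative sets must be nonempty")
    if pos & neg:
        raise TaxonomyError(f"positive/negative sets overlap: {sorted(pos & neg)}")


def _set_name(codes: Iterable[str]) -> str:
    return "+".join(sorted(codes))


@dataclass
class LabelTaxonomy:
    """A two-level label tree: named groups partitioning the leaf classes.

    ``groups`` maps group name to the ordered list of member leaf codes;
    the declaration order of the groups fixes the root task's positive
    side (first group is positive).
    """

    groups: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)  # code -> ClassLabel

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if len(self.groups) < 2:
            raise TaxonomyError("a taxonomy needs at least two groups")
        seen: set = set()
        for name, members in self.groups.items():
            if len(members) < 2:
                raise TaxonomyError(f"group {name!r} has fewer than 2 children")
            dup = seen & set(members)
            if dup:
                raise TaxonomyError(f"leaf codes appear in two groups: {sorted(dup)}")
            if len(set(members)) != len(members):
                raise TaxonomyError(f"group {name!r} repeats a leaf code")
            seen |= set(members)
        for code in self.labels:
            if code not in seen:
                raise TaxonomyError(f"label {code!r} belongs to no group")

    @property
    def leaves(self) -> frozenset:
        return frozenset(c for members in self.groups.values() for c in members)

    @property
    def group_names(self) -> list:
        return list(self.groups)

    def group_of(self, code: str) -> str:
        for name, members in self.groups.items():
            if code in members:
                return name
        raise TaxonomyError(f"unknown leaf code {code!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"groups": {g: list(m) for g, m in self.groups.items()}}

    @classmethod
    def from_dict(cls, doc: Mapping) -> "LabelTaxonomy":
        return cls(groups={g: list(m) for g, m in doc["groups"].items()})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "LabelTaxonomy":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


#: Display names for the six default lesion classes.
DEFAULT_LABELS = {
    "ACK": "Actinic Keratosis",
    "NEV": "Nevus",
    "SEK": "Seborrheic Keratosis",
    "MEL": "Melanoma",
    "BCC": "Basal Cell Carcinoma",
    "SCC": "Squamous Cell Carcinoma",
}

#: Peel order used by the published reference structure: ACK is isolated
#: first within Benign, MEL first within Malignant.
DEFAULT_PEEL_ORDER = {
    "Benign": ["ACK", "NEV", "SEK"],
    "Malignant": ["MEL", "BCC", "SCC"],
}


def default_taxonomy() -> LabelTaxonomy:
    """The six-class dermatological tree: Benign={ACK,NEV,SEK}, Malignant={MEL,BCC,SCC}."""
    return LabelTaxonomy(
        groups={"Benign": ["ACK", "NEV", "SEK"], "Malignant": ["MEL", "BCC", "SCC"]},
        labels={c: ClassLabel(c, n) for c, n in DEFAULT_LABELS.items()},
    )


def candidate_tasks(taxonomy: LabelTaxonomy) -> list:
    """Every binary task investigated when building the hierarchy.

    Returns, in deterministic order (stage, group name, sorted positive
    codes): the root group-vs-group task, each group's one-vs-rest peel
    tasks, and for each peeled class the residual pair task among the two
    remaining classes.  A two-child group contributes only its two
    (equivalent) peel tasks — the residual of a pair is empty.

    For the default 6-class tree this yields 13 tasks:
    1 root + 3 + 3 peels + 3 + 3 residual pairs.
    """
    taxonomy.validate()
    tasks: list = []
    names = taxonomy.group_names
    first = frozenset(taxonomy.groups[names[0]])
    rest = frozenset(c for n in names[1:] for c in taxonomy.groups[n])
    tasks.append(
        BinaryTask(
            task_name=f"{names[0]} vs {'+'.join(names[1:])}",
            positive_set=first,
            negative_set=rest,
            stage="root",
        )
    )
    peels, pairs = [], []
    for gname in sorted(names):
        members = taxonomy.groups[gname]
        for code in sorted(members):
            others = frozenset(members) - {code}
            peels.append(
                BinaryTask(
                    task_name=f"{code} vs {_set_name(others)}",
                    positive_set=frozenset({code}),
                    negative_set=others,
                    stage="group_peel",
                )
            )
            if len(others) >= 2:
                a, *b = sorted(others)
                pair = BinaryTask(
                    task_name=f"{a} vs {_set_name(b)}",
                    positive_set=frozenset({a}),
                    negative_set=frozenset(b),
                    stage="residual_pair",
                )
                if pair not in pairs:
                    pairs.append(pair)
    # Residual pairs of a 3-child group coincide pairwise only when two
    # peels leave the same remaining pair; dedupe keeps first occurrence.
    seen: set = set()
    deduped = []
    for t in pairs:
        key = (t.positive_set, t.negative_set)
        if key not in seen:
            seen.add(key)
            deduped.append(t)
    tasks.extend(sorted(peels, key=_task_key))
    tasks.extend(sorted(deduped, key=_task_key))
    return tasks


def _task_key(task: BinaryTask):
    return (STAGES.index(task.stage), tuple(sorted(task.positive_set)), tuple(sorted(task.negative_set)))


def decision_nodes(taxonomy: LabelTaxonomy, peel_order: Mapping | None = None) -> list:
    """Nodes of the assembled tree under a given peel order.

    ``peel_order`` maps each group name to its children in the order they
    are peeled off; the last two children form the terminal pair node.
    For the default taxonomy with the default order this produces the five
    nodes  Benign|Malignant, ACK|NEV+SEK, NEV|SEK, MEL|BCC+SCC, BCC|SCC.
    """
    taxonomy.validate()
    if peel_order is None:
        peel_order = {g: list(m) for g, m in taxonomy.groups.items()}
    for gname, members in taxonomy.groups.items():
        order = peel_order.get(gname)
        if order is None or sorted(order) != sorted(members):
            raise TaxonomyError(
                f"peel_order for group {gname!r} must list its children exactly once"
            )

    names = taxonomy.group_names
    nodes: list = []
    root_pos = frozenset(taxonomy.groups[names[0]])
    root_neg = frozenset(c for n in names[1:] for c in taxonomy.groups[n])
    root = DecisionNode(
        node_id=f"{names[0]}|{names[1] if len(names) == 2 else _set_name(root_neg)}",
        positive_set=root_pos,
        negative_set=root_neg,
        parent_branch=None,
    )
    nodes.append(root)
    for i, gname in enumerate(names):
        branch = "positive" if i == 0 else "negative"
        if len(names) > 2 and i > 0:
            raise TaxonomyError("more than two groups require a nested root; not supported")
        parent_id, parent_branch = root.node_id, branch
        remaining = list(peel_order[gname])
        while len(remaining) > 2:
            code, remaining = remaining[0], remaining[1:]
            node = DecisionNode(
                node_id=f"{code}|{_set_name(remaining)}",
                positive_set=frozenset({code}),
                negative_set=frozenset(remaining),
                parent_branch=(parent_id, parent_branch),
            )
            nodes.append(node)
            parent_id, parent_branch = node.node_id, "negative"
        a, b = remaining
        nodes.append(
            DecisionNode(
                node_id=f"{a}|{b}",
                positive_set=frozenset({a}),
                negative_set=frozenset({b}),
                parent_branch=(parent_id, parent_branch),
            )
        )
    return nodes


def enumerate_training_runs(
    nodes: Sequence, architectures: Sequence[str]
) -> list:
    """Cartesian product of decision nodes (or tasks) and backbone names.

    Each node is trained with each candidate architecture, so the number
    of training runs is ``|nodes| x |architectures|`` — e.g. the assembled
    5-node tree with 4 candidate backbones gives 20 runs.
    """
    if not nodes or not architectures:
        raise TaxonomyError("nodes and architectures must both be nonempty")
    return [(arch, node) for node, arch in product(nodes, architectures)]


def route_outcomes(nodes: Sequence) -> dict:
    """Map every combination of binary outcomes to the leaf it reaches.

    Used by property tests to check routing totality: walking the node
    list from the root and branching on each node's outcome must reach
    every leaf by exactly one root-to-leaf path.
    """
    by_id = {n.node_id: n for n in nodes}
    root = next(n for n in nodes if n.parent_branch is None)
    paths: dict = {}

    def walk(node: DecisionNode, path: tuple) -> None:
        for branch, side in (("positive", node.positive_set), ("negative", node.negative_set)):
            child = next(
                (c for c in nodes if c.parent_branch == (node.node_id, branch)), None
            )
            if child is not None:
                walk(child, path + ((node.node_id, branch),))
            else:
                if len(side) != 1:
                    raise TaxonomyError(
                        f"terminal branch of {node.node_id!r} holds {sorted(side)}"
                    )
                (leaf,) = side
                paths.setdefault(leaf, []).append(path + ((node.node_id, branch),))

    walk(root, ())
    assert set(paths) <= {c for n in by_id.values() for c in n.reachable}
    return paths
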