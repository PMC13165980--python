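"""Recall-first model selection, hierarchy assembly, routing, evaluation.

Each decision node of the taxonomy is trained with every candidate
backbone; the node's model is then chosen by the recall-first rule:
maximize recall, breaking ties by F1-score, then precision, then
accuracy (registration order as the final, documented tie-break).
Recall here is the task's positive-class recall for binary nodes and
macro recall for multi-class candidates — always compared unrounded.
False negatives are the clinically costly error for lesion triage,
which is why recall outranks every other metric.

The chosen models are assembled into a tree of binary classifiers;
a test image enters at the root and follows the higher-scoring branch
at each node (argmax of the two softmax scores, ties to the positive
branch) until it reaches a leaf class.  Evaluation reports the
six-class confusion matrix, its benign/malignant collapse and the
seven-metric report, plus a comparison table against a flat
multi-class baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .backbones import TrainedModel, predict_scores
from .datapipe import ImageRecord
from .metrics import ConfusionMatrix, MetricReport, confusion_from_predictions, report
from .taxonomy import DecisionNode, LabelTaxonomy, TaxonomyError, decision_nodes

__all__ = [
    "CandidateResult",
    "NodeAssignment",
    "HierarchicalClassifier",
    "SelectionError",
    "select_best",
    "select_group_split",
    "assemble",
    "route",
    "evaluate_hierarchy",
    "compare_structures",
    "compare_reports",
    "relabel_for_node",
    "node_training_pool",
]


class SelectionError(ValueError):
    pass


@dataclass
class CandidateResult:
    """One backbone's evaluation on one binary (or multi-class) task."""

    backbone_name: str
    task_name: str
    metrics: MetricReport
    registration_index: int = 0
    model: TrainedModel | None = None

    def selection_key(self) -> tuple:
        """Lexicographic key: recall, f1, precision, accuracy, then
        earlier registration wins (negated index)."""
        km = self.metrics.key_metrics()
        return (
            km["recall"],
            km["f1"],
            km["precision"],
            km["accuracy"],
            -self.registration_index,
        )


def select_best(candidates: Sequence[CandidateResult]) -> CandidateResult:
    """The candidate maximal under (recall, f1, precision, accuracy)."""
    if not candidates:
        raise SelectionError("no candidates to select from")
    return max(candidates, key=CandidateResult.selection_key)


def select_group_split(group_results: Mapping[str, CandidateResult]) -> str:
    """Which class to peel first: the one whose best one-vs-rest
    candidate wins under the same lexicographic key.

    ``group_results`` maps each child class of the group to the best
    candidate of its one-vs-rest task.  Ties fall to the alphabetically
    first class (deterministic).
    """
    if not group_results:
        raise SelectionError("group_results is empty")
    return max(
        sorted(group_results),
        key=lambda code: group_results[code].selection_key(),
    )


@dataclass
class NodeAssignment:
    """Chosen backbone (and optional trained model) per decision node."""

    backbones: dict  # node_id -> backbone name
    models: dict = field(default_factory=dict)  # node_id -> TrainedModel/callable

    def to_json(self) -> str:
        return json.dumps({"backbones": self.backbones})

    @classmethod
    def from_file(cls, path: Path | str) -> "NodeAssignment":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(backbones=dict(doc["backbones"]))


@dataclass
class HierarchicalClassifier:
    """An assembled tree of binary decision models."""

    taxonomy: LabelTaxonomy
    nodes: list  # ordered DecisionNode list, root first
    assignment: NodeAssignment
    name: str = "hierarchy"
    peel_order: dict | None = None

    def __post_init__(self) -> None:
        ids = {n.node_id for n in self.nodes}
        missing = ids - set(self.assignment.backbones)
        if missing:
            raise SelectionError(f"nodes without an assigned model: {sorted(missing)}")
        roots = [n for n in self.nodes if n.parent_branch is None]
        if len(roots) != 1:
            raise SelectionError("classifier must have exactly one root node")
        # every leaf reachable by exactly one path
        reached = _leaf_paths(self.nodes)
        leaves = self.taxonomy.leaves
        if set(reached) != set(leaves) or any(len(p) != 1 for p in reached.values()):
            raise SelectionError("routing is not total over the taxonomy's leaves")

    @property
    def root(self) -> DecisionNode:
        return next(n for n in self.nodes if n.parent_branch is None)

    def child(self, node: DecisionNode, branch: str) -> DecisionNode | None:
        return next(
            (c for c in self.nodes if c.parent_branch == (node.node_id, branch)), None
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "name": self.name,
                "taxonomy": self.taxonomy.to_dict(),
                "peel_order": self.peel_order,
                "nodes": self.assignment.backbones,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str, name: str | None = None) -> "HierarchicalClassifier":
        doc = yaml.safe_load(text)
        return assemble(
            LabelTaxonomy.from_dict(doc["taxonomy"]),
            doc.get("peel_order"),
            doc["nodes"],
            name=name or doc.get("name", "hierarchy"),
        )


def _leaf_paths(nodes: Sequence[DecisionNode]) -> dict:
    root = next(n for n in nodes if n.parent_branch is None)
    paths: dict = {}

    def walk(node, path):
        for branch, side in (("positive", node.positive_set), ("negative", node.negative_set)):
            child = next(
                (c for c in nodes if c.parent_branch == (node.node_id, branch)), None
            )
            if child is not None:
                walk(child, path + [(node.node_id, branch)])
            elif len(side) == 1:
                (leaf,) = side
                paths.setdefault(leaf, []).append(path + [(node.node_id, branch)])
            else:
                raise SelectionError(
                    f"terminal branch of {node.node_id} still holds {sorted(side)}"
                )

    walk(root, [])
    return paths


def assemble(
    taxonomy: LabelTaxonomy,
    peel_order: Mapping[str, Sequence[str]] | None,
    assignment: NodeAssignment | Mapping[str, str],
    name: str = "hierarchy",
) -> HierarchicalClassifier:
    """Build and validate the classifier for a taxonomy and peel order."""
    nodes = decision_nodes(taxonomy, peel_order)
    if not isinstance(assignment, NodeAssignment):
        assignment = NodeAssignment(backbones=dict(assignment))
    return HierarchicalClassifier(
        taxonomy=taxonomy,
        nodes=nodes,
        assignment=assignment,
        name=name,
        peel_order=None if peel_order is None else {g: list(v) for g, v in peel_order.items()},
    )


def route(classifier: HierarchicalClassifier, node_scores: Mapping[str, tuple]) -> str:
    """Follow argmax branches from the root to a leaf.

    ``node_scores`` maps node ids to ``(positive_score, negative_score)``
    pairs for at least the nodes along the taken path; exact ties go to
    the positive branch.
    """
    node = classifier.root
    while True:
        if node.node_id not in node_scores:
            raise SelectionError(f"no scores for node {node.node_id!r} on the taken path")
        pos, neg = node_scores[node.node_id]
        branch = "positive" if pos >= neg else "negative"
        side = node.positive_set if branch == "positive" else node.negative_set
        child = classifier.child(node, branch)
        if child is None:
            if len(side) != 1:
                raise SelectionError(f"dangling branch at {node.node_id!r}")
            (leaf,) = side
            return leaf
        node = child


# -- node training pools ---------------------------------------------------

def relabel_for_node(record: ImageRecord, node: DecisionNode) -> str:
    """The binary label ('positive'/'negative') a record carries at a node."""
    if record.label in node.positive_set:
        return "positive"
    if record.label in node.negative_set:
        return "negative"
    raise SelectionError(f"label {record.label!r} does not reach node {node.node_id!r}")


def node_training_pool(records: Sequence[ImageRecord], node: DecisionNode) -> list:
    """Records reaching the node, relabeled to positive/negative.

    The root sees every class; an inner node sees only the classes in
    its positive or negative set.  Returned records are shallow copies
    with the binary label.
    """
    from dataclasses import replace

    pool = []
    for r in records:
        if r.label in node.positive_set or r.label in node.negative_set:
            pool.append(replace(r, label=relabel_for_node(r, node)))
    return pool


# -- evaluation ------------------------------------------------------------

def _node_predictor(classifier: HierarchicalClassifier, node_id: str) -> Callable:
    model = classifier.assignment.models.get(node_id)
    if model is None:
        raise SelectionError(
            f"node {node_id!r} has no trained model attached; "
            "evaluation needs assignment.models"
        )
    if isinstance(model, TrainedModel):
        if model.class_order != ["positive", "negative"]:
            raise SelectionError(
                f"node {node_id!r} model must be trained with class order "
                "['positive', 'negative']"
            )
        return lambda recs: predict_scores(model, recs).to_numpy()
    return model  # stub predictor: callable(records) -> (n, 2) scores


def evaluate_hierarchy(
    classifier: HierarchicalClassifier, test: Sequence[ImageRecord]
) -> dict:
    """Route every test image through the assembled tree and score it.

    Returns ``six_class`` (the K-way confusion matrix of final leaf
    predictions), ``group_level`` (the same predictions collapsed to the
    taxonomy's groups — benign vs malignant by default), ``report``
    (seven metrics on the K-way matrix) and the raw per-image
    predictions.
    """
    test = list(test)
    if not test:
        raise SelectionError("empty test set")
    if any(r.is_augmented for r in test):
        raise SelectionError("test records must be unaugmented originals")

    predictions = [None] * len(test)
    # breadth-first: batch all images that reach each node
    frontier = [(classifier.root, list(range(len(test))))]
    while frontier:
        node, idxs = frontier.pop()
        scores = _node_predictor(classifier, node.node_id)([test[i] for i in idxs])
        scores = np.asarray(scores)
        if scores.shape != (len(idxs), 2):
            raise SelectionError(
                f"node {node.node_id!r} predictor returned shape {scores.shape}"
            )
        take_pos = scores[:, 0] >= scores[:, 1]
        for branch, mask in (("positive", take_pos), ("negative", ~take_pos)):
            sub = [i for i, m in zip(idxs, mask) if m]
            if not sub:
                continue
            side = node.positive_set if branch == "positive" else node.negative_set
            child = classifier.child(node, branch)
            if child is None:
                (leaf,) = side
                for i in sub:
                    predictions[i] = leaf
            else:
                frontier.append((child, sub))

    class_order = sorted(classifier.taxonomy.leaves)
    six = confusion_from_predictions([r.label for r in test], predictions, class_order)
    mapping = {c: classifier.taxonomy.group_of(c) for c in class_order}
    group = six.collapse(mapping, classifier.taxonomy.group_names)
    return {
        "six_class": six,
        "group_level": group,
        "report": report(six),
        "predictions": predictions,
    }


def train_hierarchy(
    train: Sequence[ImageRecord],
    taxonomy: LabelTaxonomy,
    backbone_spec,
    config,
    peel_order: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> HierarchicalClassifier:
    """Train one backbone per decision node and assemble the classifier.

    Every node model is trained on the full training pool relabeled for
    that node's task (all classes reach the root; only a group's classes
    reach its inner nodes).
    """
    from .backbones import build_backbone, finetune

    nodes = decision_nodes(taxonomy, peel_order)
    models, backbones = {}, {}
    for node in nodes:
        pool = node_training_pool(train, node)
        model = build_backbone(backbone_spec, 2, ["positive", "negative"], seed=seed)
        model.task_name = node.node_id
        finetune(model, pool, None, config)
        models[node.node_id] = model
        backbones[node.node_id] = backbone_spec.name
    return HierarchicalClassifier(
        taxonomy=taxonomy,
        nodes=nodes,
        assignment=NodeAssignment(backbones=backbones, models=models),
        peel_order=None if peel_order is None else {g: list(v) for g, v in peel_order.items()},
    )


def hierarchy_vs_flat(
    seed: int,
    per_class: int = 72,
    image_size: int = 64,
    epochs: int = 10,
    mini_batch_size: int = 16,
) -> dict:
    """Desk-scale comparison of the assembled hierarchy and a flat model.

    Generates a synthetic group-structured dataset, splits 80/20, trains
    one small CNN per decision node and one flat six-way small CNN under
    the same epoch budget, and evaluates both on the shared test side.
    Returns the two macro recalls (percent) and the full reports.  The
    defaults are the package's standard desk-scale study conditions:
    ~60 training images per class at 64 px with a <=20-epoch budget.
    """
    from .backbones import BackboneSpec, TrainingConfig, build_backbone, predict_labels
    from .datapipe import SplitSpec, split_dataset
    from .synthgen import generate_dataset
    from .taxonomy import default_taxonomy

    records = generate_dataset(per_class_counts=per_class, image_size=image_size, seed=seed)
    train, test = split_dataset(records, SplitSpec(0.2, seed=seed))
    taxonomy = default_taxonomy()
    spec = BackboneSpec("tiny_test_cnn", image_size)
    config = TrainingConfig(max_epochs=epochs, mini_batch_size=mini_batch_size, seed=seed)

    clf = train_hierarchy(train, taxonomy, spec, config, seed=seed)
    hier = evaluate_hierarchy(clf, test)

    order = sorted(taxonomy.leaves)
    flat = build_backbone(spec, len(order), order, seed=seed)
    from .backbones import finetune

    finetune(flat, train, None, config)
    pred = predict_labels(flat, test)
    conf = confusion_from_predictions([r.label for r in test], pred, order)
    flat_report = report(conf)
    return {
        "hierarchy_macro_recall": hier["report"].macro["recall"],
        "flat_macro_recall": flat_report.macro["recall"],
        "hierarchy_report": hier["report"],
        "flat_report": flat_report,
        "n_train": len(train),
        "n_test": len(test),
    }


def compare_reports(
    named_macros: Mapping[str, Mapping[str, float]], baseline_name: str
) -> pd.DataFrame:
    """Comparison table from macro metric mappings, with differences vs
    the named baseline appended as ``delta_<metric>`` columns."""
    if baseline_name not in named_macros:
        raise SelectionError(f"baseline {baseline_name!r} missing from inputs")
    df = pd.DataFrame(named_macros).T
    base = df.loc[baseline_name]
    for col in list(df.columns):
        df[f"delta_{col}"] = df[col] - base[col]
    return df


def compare_structures(
    structures: Mapping[str, HierarchicalClassifier],
    baseline: TrainedModel,
    test: Sequence[ImageRecord],
    baseline_name: str = "multiclass_baseline",
) -> pd.DataFrame:
    """Evaluate each structure and the flat baseline on one test set."""
    from .backbones import predict_labels

    macros = {}
    pred = predict_labels(baseline, test)
    conf = confusion_from_predictions([r.label for r in test], pred, baseline.class_order)
    macros[baseline_name] = report(conf).macro
    for name, clf in structures.items():
        macros[name] = evaluate_hierarchy(clf, test)["report"].macro
    return compare_reports(macros, baseline_name)
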