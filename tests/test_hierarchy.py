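"""Selection cascade, assembly, routing and hierarchical evaluation."""

import itertools

import numpy as np
import pytest

import lesiontree as lt
from lesiontree.hierarchy import (
    CandidateResult,
    NodeAssignment,
    SelectionError,
    assemble,
    compare_reports,
    evaluate_hierarchy,
    node_training_pool,
    route,
    select_best,
    select_group_split,
)
from lesiontree.metrics import MetricReport
from lesiontree.reference import (
    BENIGN_PEELS,
    MALIGNANT_PEELS,
    NEV_VS_SEK,
    STRUCTURE_COMPARISON,
    STRUCTURE_PRESETS,
    candidates_from_rows,
)
from conftest import perfect_stub


def row_candidate(name, recall, f1=50.0, precision=50.0, accuracy=50.0, index=0):
    return CandidateResult(
        backbone_name=name,
        task_name="t",
        metrics=MetricReport.from_binary_row(
            "positive", accuracy=accuracy, precision=precision, recall=recall, f1=f1
        ),
        registration_index=index,
    )


# -- selection -------------------------------------------------------------

def test_select_best_prefers_recall_over_other_metrics():
    """The published NEV-vs-SEK rows: the recall 93.06 candidate wins even
    though another model beats it on accuracy, precision and F1."""
    best = select_best(candidates_from_rows(NEV_VS_SEK, "NEV", "NEV|SEK"))
    assert best.backbone_name == "mobilenetv2"
    assert best.metrics.key_metrics()["recall"] == 93.06


def test_select_best_single_candidate():
    c = row_candidate("only", 50.0)
    assert select_best([c]) is c


def test_select_best_tiebreak_cascade():
    a = row_candidate("a", recall=90.0, f1=72.0, index=0)
    b = row_candidate("b", recall=90.0, f1=71.0, index=1)
    assert select_best([a, b]).backbone_name == "a"
    c = row_candidate("c", recall=90.0, f1=72.0, precision=60.0, index=2)
    assert select_best([a, c]).backbone_name == "c"
    d = row_candidate("d", recall=90.0, f1=72.0, precision=60.0, accuracy=55.0, index=3)
    assert select_best([c, d]).backbone_name == "d"
    # full tie: registration order decides
    e = row_candidate("e", recall=90.0, f1=72.0, precision=60.0, accuracy=55.0, index=4)
    assert select_best([d, e]).backbone_name == "d"


def test_select_best_permutation_invariant():
    cands = candidates_from_rows(NEV_VS_SEK, "NEV", "NEV|SEK")
    for perm in itertools.permutations(cands):
        assert select_best(list(perm)).backbone_name == "mobilenetv2"


def test_selected_recall_dominates_all_candidates():
    cands = candidates_from_rows(NEV_VS_SEK, "NEV", "NEV|SEK")
    best = select_best(cands)
    assert all(
        best.metrics.key_metrics()["recall"] >= c.metrics.key_metrics()["recall"]
        for c in cands
    )


def test_select_best_empty_rejected():
    with pytest.raises(SelectionError):
        select_best([])


def test_group_split_choices_match_published_structure():
    """Best one-vs-rest candidates pick ACK first in Benign and MEL first
    in Malignant, the peel order of the published hierarchy."""
    benign = {
        code: select_best(candidates_from_rows(rows, code, f"{code}|rest"))
        for code, rows in BENIGN_PEELS.items()
    }
    assert select_group_split(benign) == "ACK"
    malignant = {
        code: select_best(candidates_from_rows(rows, code, f"{code}|rest"))
        for code, rows in MALIGNANT_PEELS.items()
    }
    assert select_group_split(malignant) == "MEL"


def test_group_split_two_children():
    res = {"x": row_candidate("m", 80.0), "y": row_candidate("m", 70.0)}
    assert select_group_split(res) == "x"


def test_group_split_missing_child_rejected():
    with pytest.raises(SelectionError):
        select_group_split({})


# -- assembly --------------------------------------------------------------

def test_assemble_published_structures_are_valid():
    tax = lt.default_taxonomy()
    for name, mapping in STRUCTURE_PRESETS.items():
        clf = assemble(tax, lt.DEFAULT_PEEL_ORDER, mapping, name=name)
        assert len(clf.nodes) == 5
        assert clf.assignment.backbones["Benign|Malignant"] == "mobilenetv2"


def test_assemble_missing_node_rejected():
    tax = lt.default_taxonomy()
    incomplete = dict(STRUCTURE_PRESETS["structure-1"])
    incomplete.pop("NEV|SEK")
    with pytest.raises(SelectionError):
        assemble(tax, lt.DEFAULT_PEEL_ORDER, incomplete)


def test_structure_yaml_roundtrip():
    clf = assemble(lt.default_taxonomy(), lt.DEFAULT_PEEL_ORDER,
                   STRUCTURE_PRESETS["structure-2"], name="structure-2")
    from lesiontree.hierarchy import HierarchicalClassifier

    again = HierarchicalClassifier.from_yaml(clf.to_yaml())
    assert again.assignment.backbones == clf.assignment.backbones
    assert [n.node_id for n in again.nodes] == [n.node_id for n in clf.nodes]


# -- routing ---------------------------------------------------------------

def make_classifier():
    return assemble(lt.default_taxonomy(), lt.DEFAULT_PEEL_ORDER,
                    STRUCTURE_PRESETS["structure-1"])


def test_route_forced_path():
    clf = make_classifier()
    scores = {
        "Benign|Malignant": (0.1, 0.9),  # -> Malignant
        "MEL|BCC+SCC": (0.2, 0.8),  # -> rest
        "BCC|SCC": (0.3, 0.7),  # -> SCC
    }
    assert route(clf, scores) == "SCC"


def test_route_all_ties_take_positive_branches():
    clf = make_classifier()
    scores = {n.node_id: (0.5, 0.5) for n in clf.nodes}
    # positive everywhere: Benign -> ACK
    assert route(clf, scores) == "ACK"


def test_route_missing_score_on_path_rejected():
    clf = make_classifier()
    with pytest.raises(SelectionError):
        route(clf, {"Benign|Malignant": (0.9, 0.1)})  # next node missing


def test_route_outcome_enumeration_reaches_each_leaf_once():
    """All 2^5 outcome combinations reach exactly the six leaves, each
    via one combination of the on-path decisions."""
    clf = make_classifier()
    node_ids = [n.node_id for n in clf.nodes]
    reached = {}
    for bits in itertools.product([0, 1], repeat=len(node_ids)):
        scores = {
            nid: ((1.0, 0.0) if b else (0.0, 1.0))
            for nid, b in zip(node_ids, bits)
        }
        leaf = route(clf, scores)
        reached.setdefault(leaf, set()).add(bits)
    assert set(reached) == lt.default_taxonomy().leaves
    # each leaf's on-path decision pattern is unique: 32 total outcomes
    # collapse onto 6 leaves with multiplicity 2^(off-path nodes)
    assert sum(len(v) for v in reached.values()) == 32


# -- evaluation ------------------------------------------------------------

def stub_models(clf, predict_factory=perfect_stub):
    return {n.node_id: predict_factory(n) for n in clf.nodes}


def test_evaluate_perfect_stubs_diagonal(small_split):
    _, test = small_split
    clf = make_classifier()
    clf.assignment.models = stub_models(clf)
    result = evaluate_hierarchy(clf, test)
    six = result["six_class"]
    assert np.array_equal(six.counts, np.diag(np.diag(six.counts)))
    assert result["report"].macro["recall"] == pytest.approx(100.0)
    assert np.all(result["group_level"].counts == np.diag(np.diag(result["group_level"].counts)))


def test_evaluate_root_always_benign_empties_malignant_column(small_split):
    _, test = small_split
    clf = make_classifier()
    models = stub_models(clf)
    models["Benign|Malignant"] = lambda recs: np.tile([1.0, 0.0], (len(recs), 1))
    clf.assignment.models = models
    result = evaluate_hierarchy(clf, test)
    g = result["group_level"]
    mal = g.class_order.index("Malignant")
    assert g.counts[:, mal].sum() == 0


def test_evaluate_count_conservation_and_collapse_consistency(small_split):
    _, test = small_split
    clf = make_classifier()
    rng_global = np.random.default_rng(123)

    def noisy_stub(node, flip=0.3):
        def predict(records):
            out = []
            for r in records:
                correct = r.label in node.positive_set
                if rng_global.random() < flip:
                    correct = not correct
                out.append([1.0, 0.0] if correct else [0.0, 1.0])
            return np.array(out)

        return predict

    clf.assignment.models = {n.node_id: noisy_stub(n) for n in clf.nodes}
    result = evaluate_hierarchy(clf, test)
    six = result["six_class"]
    truth_hist = lt.class_histogram(test)
    for i, code in enumerate(six.class_order):
        assert six.counts[i].sum() == truth_hist[code]
    # collapsing six_class reproduces group_level exactly
    mapping = {c: lt.default_taxonomy().group_of(c) for c in six.class_order}
    collapsed = six.collapse(mapping, ["Benign", "Malignant"])
    assert np.array_equal(collapsed.counts, result["group_level"].counts)


def test_evaluate_matches_independent_routing_simulation(small_split):
    """Stub models with deterministic per-image node outcomes: the
    evaluation must equal a direct simulation of the decision chain."""
    _, test = small_split
    clf = make_classifier()

    def outcome(record, node):  # deterministic pseudo-random error
        h = hash((record.image_id, node.node_id)) % 10
        correct = record.label in node.reachable and h < 7
        truth_pos = record.label in node.positive_set
        return truth_pos if correct else not truth_pos

    def stub(node):
        def predict(records):
            return np.array(
                [[1.0, 0.0] if outcome(r, node) else [0.0, 1.0] for r in records]
            )

        return predict

    clf.assignment.models = {n.node_id: stub(n) for n in clf.nodes}
    result = evaluate_hierarchy(clf, test)

    # independent oracle: walk the tree per image
    def simulate(record):
        node = clf.root
        while True:
            branch = "positive" if outcome(record, node) else "negative"
            side = node.positive_set if branch == "positive" else node.negative_set
            child = clf.child(node, branch)
            if child is None:
                (leaf,) = side
                return leaf
            node = child

    expected = [simulate(r) for r in test]
    assert result["predictions"] == expected


def test_evaluate_rejects_augmented_test(small_split):
    train, test = small_split
    clf = make_classifier()
    clf.assignment.models = stub_models(clf)
    bad = lt.augment_image(
        test[0], lt.AugmentationConfig(output_size=32, target_per_class=5),
        np.random.default_rng(0),
    )
    with pytest.raises(SelectionError):
        evaluate_hierarchy(clf, [bad])


# -- comparison ------------------------------------------------------------

def test_compare_reports_published_recall_difference():
    table = compare_reports(STRUCTURE_COMPARISON, "multiclass_baseline")
    assert table.loc["structure-1", "delta_recall"] == pytest.approx(22.35)
    assert table.loc["multiclass_baseline", "delta_recall"] == 0.0


def test_compare_structure_with_itself_all_zero():
    table = compare_reports(
        {"a": STRUCTURE_COMPARISON["structure-1"],
         "base": STRUCTURE_COMPARISON["structure-1"]},
        "base",
    )
    assert all(table.loc["a", f"delta_{m}"] == 0 for m in ("recall", "accuracy"))


def test_compare_table_row_count():
    table = compare_reports(STRUCTURE_COMPARISON, "multiclass_baseline")
    assert len(table) == 5  # baseline + four structures


def test_compare_structures_with_models(small_split, tiny_spec32, quick_config):
    """End-to-end comparison table: a trained flat baseline against a
    stub-perfect hierarchy on the shared test set."""
    from lesiontree.hierarchy import compare_structures

    train, test = small_split
    order = sorted({r.label for r in train})
    baseline = lt.build_backbone(tiny_spec32, 6, order, seed=0)
    lt.finetune(baseline, train, None, quick_config)

    clf = make_classifier()
    clf.assignment.models = stub_models(clf)
    table = compare_structures({"perfect-hierarchy": clf}, baseline, test)
    assert set(table.index) == {"multiclass_baseline", "perfect-hierarchy"}
    assert table.loc["perfect-hierarchy", "recall"] == pytest.approx(100.0)
    assert table.loc["perfect-hierarchy", "delta_recall"] == pytest.approx(
        100.0 - table.loc["multiclass_baseline", "recall"]
    )


def test_node_training_pool_relabels_and_filters(small_dataset):
    nodes = lt.decision_nodes(lt.default_taxonomy())
    root_pool = node_training_pool(small_dataset, nodes[0])
    assert len(root_pool) == len(small_dataset)
    assert set(r.label for r in root_pool) == {"positive", "negative"}
    pair_pool = node_training_pool(small_dataset, nodes[2])  # NEV|SEK
    assert len(pair_pool) == sum(
        1 for r in small_dataset if r.label in ("NEV", "SEK")
    )
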