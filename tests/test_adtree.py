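"""Alternating decision tree: fitting, scoring, extraction, serialization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import adirshort as a
from adirshort.adtree import (
    ADTreeModel,
    ModelFormatError,
    PredictionNode,
    SplitterNode,
    TrainingConfig,
)
from adirshort.instrument import ValidationError

from conftest import matrix_from_arrays
from oracles import (
    oracle_exponential_loss,
    oracle_fit_adtree,
    oracle_predict,
    same_tree,
)


def hand_built_tree():
    """root 0.5; splitter(q<1): low −2.0 with nested splitter(r<2) children
    −0.5/+0.1; high +1.0.  Items: q=1, r=2."""
    nested = SplitterNode(
        item_id=2, threshold=2.0,
        low_child=PredictionNode(-0.5), high_child=PredictionNode(0.1),
    )
    low = PredictionNode(-2.0, children=[nested])
    high = PredictionNode(1.0)
    root = PredictionNode(0.5, children=[
        SplitterNode(item_id=1, threshold=1.0, low_child=low, high_child=high)
    ])
    return ADTreeModel(root=root, iterations_used=2, item_order=[1, 2])


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def test_predict_score_root_only():
    model = ADTreeModel(root=PredictionNode(0.4), iterations_used=0, item_order=[])
    assert a.predict_score(model, {1: 0}) == pytest.approx(0.4)


def test_predict_score_sums_all_reached_nodes():
    model = hand_built_tree()
    assert a.predict_score(model, {1: 0, 2: 0}) == pytest.approx(-2.0)
    assert a.predict_score(model, {1: 2, 2: 0}) == pytest.approx(1.5)
    assert a.predict_score(model, {1: 2, 2: 2}) == pytest.approx(1.5)


def test_predict_score_missing_item_names_it():
    with pytest.raises(ValidationError, match="item 2"):
        a.predict_score(hand_built_tree(), {1: 0})


def test_predict_matches_path_enumeration_oracle():
    rng = np.random.default_rng(2)
    m = matrix_from_arrays(rng.integers(0, 3, size=(40, 4)),
                           rng.choice([-1, 1], size=40))
    model = a.fit_adtree(m, TrainingConfig(iterations=4))
    oracle = oracle_fit_adtree(m.scores.tolist(), m.labels.tolist(),
                               m.item_ids, iterations=4)
    for i in range(m.n_subjects):
        x = m.row_mapping(i)
        assert a.predict_score(model, x) == pytest.approx(oracle_predict(oracle, x))
    # vectorised scorer agrees with the recursive one
    vec = a.score_matrix(model, m)
    assert vec == pytest.approx([a.predict_score(model, m.row_mapping(i))
                                 for i in range(m.n_subjects)])


def test_predict_piecewise_constant_between_thresholds():
    model = hand_built_tree()
    # moving within a threshold cell never changes the score
    assert a.predict_score(model, {1: 1, 2: 0}) == a.predict_score(model, {1: 2, 2: 1})


@pytest.mark.parametrize(
    "score,label,confidence,flagged",
    [
        (-3.2, a.AUTISM, 3.2, False),
        (0.179, a.NON_SPECTRUM, 0.179, True),
        (0.0, a.NON_SPECTRUM, 0.0, True),
        (2.0, a.NON_SPECTRUM, 2.0, False),
        (-0.3, a.AUTISM, 0.3, True),
    ],
)
def test_classify_score_sign_and_confidence(score, label, confidence, flagged):
    assert a.classify_score(score, 0.5) == (label, pytest.approx(confidence), flagged)


def test_zero_score_flagged_even_with_zero_band():
    assert a.classify_score(0.0, 0.0) == (a.NON_SPECTRUM, 0.0, True)


@given(st.floats(-5, 5, allow_nan=False))
def test_sign_consistency(score):
    label, confidence, _ = a.classify_score(score)
    assert confidence == abs(score)
    assert (label == a.AUTISM) == (score < 0)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def test_fit_empty_matrix_errors():
    m = matrix_from_arrays(np.empty((0, 2), dtype=np.int8), [])
    with pytest.raises(ValidationError):
        a.fit_adtree(m)


def test_fit_single_class_warns_and_returns_root_only():
    m = matrix_from_arrays([[0, 1], [1, 2], [2, 0]], [1, 1, 1])
    with pytest.warns(UserWarning, match="single-class"):
        model = a.fit_adtree(m, TrainingConfig(iterations=5))
    assert model.iterations_used == 0
    assert model.root.value > 0
    assert a.classify_score(a.predict_score(model, {1: 2, 2: 2}))[0] == a.NON_SPECTRUM


def test_fit_all_control_t0_classifies_non_spectrum():
    m = matrix_from_arrays([[0], [1]], [1, 1])
    model = a.fit_adtree(m, TrainingConfig(iterations=0))
    assert model.iterations_used == 0 and model.root.value > 0


def test_fit_separable_eight_records_hand_computed():
    """One informative item: +1 records score 0, −1 records score 2."""
    scores = [[0, 1]] * 4 + [[2, 1]] * 4
    labels = [1] * 4 + [-1] * 4
    m = matrix_from_arrays(scores, labels)
    model = a.fit_adtree(m, TrainingConfig(iterations=1))
    [sp] = model.root.children
    assert (sp.item_id, sp.threshold) == (1, 1.0)
    # weights all 1 after a zero-valued root: W on each side is 4 vs 0
    expected = 0.5 * math.log((4 + 1) / (0 + 1))
    assert model.root.value == pytest.approx(0.0)
    assert sp.low_child.value == pytest.approx(expected)
    assert sp.high_child.value == pytest.approx(-expected)
    preds = np.sign(a.score_matrix(model, m))
    assert preds.tolist() == labels


@pytest.mark.parametrize("trial", range(20))
def test_fit_matches_brute_force_oracle_on_small_instances(trial):
    """Chosen splits and node values equal exhaustive Z-minimisation."""
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(4, 13))
    n_items = int(rng.integers(1, 4))
    T = int(rng.integers(1, 3))
    scores = rng.integers(0, 3, size=(n, n_items))
    labels = rng.choice([-1, 1], size=n)
    if len(set(labels.tolist())) < 2:
        labels[0] = -labels[1]
    m = matrix_from_arrays(scores, labels)
    model = a.fit_adtree(m, TrainingConfig(iterations=T))
    oracle = oracle_fit_adtree(scores.tolist(), labels.tolist(), m.item_ids, T)
    assert same_tree(oracle, model.root)


def test_loss_trace_matches_independent_recomputation():
    rng = np.random.default_rng(9)
    scores = rng.integers(0, 3, size=(30, 3))
    labels = rng.choice([-1, 1], size=30)
    labels[:2] = [-1, 1]
    m = matrix_from_arrays(scores, labels)
    for T in range(4):
        model = a.fit_adtree(m, TrainingConfig(iterations=T))
        oracle = oracle_fit_adtree(scores.tolist(), labels.tolist(), m.item_ids, T)
        recomputed = oracle_exponential_loss(oracle, scores.tolist(),
                                             labels.tolist(), m.item_ids)
        assert model.loss_trace[-1] == pytest.approx(recomputed)


def test_loss_strictly_decreases_on_planted_cohort(default_matrix):
    model = a.fit_adtree(default_matrix, TrainingConfig(iterations=10))
    trace = model.loss_trace
    assert len(trace) == model.iterations_used + 1
    assert all(later < earlier for earlier, later in zip(trace, trace[1:]))


def test_fit_invariant_to_record_permutation():
    rng = np.random.default_rng(21)
    scores = rng.integers(0, 3, size=(60, 5))
    labels = rng.choice([-1, 1], size=60)
    labels[:2] = [-1, 1]
    m = matrix_from_arrays(scores, labels)
    perm = rng.permutation(60)
    m_perm = matrix_from_arrays(scores[perm], labels[perm])
    t1 = a.fit_adtree(m, TrainingConfig(iterations=5))
    t2 = a.fit_adtree(m_perm, TrainingConfig(iterations=5))
    assert a.serialize_model(t1).split('"metadata"')[0] == \
        a.serialize_model(t2).split('"metadata"')[0]


# ---------------------------------------------------------------------------
# Item extraction
# ---------------------------------------------------------------------------


def test_extract_items_counts_multiplicity():
    lo1, hi1 = PredictionNode(-0.1), PredictionNode(0.1)
    lo2, hi2 = PredictionNode(-0.2), PredictionNode(0.2)
    lo3, hi3 = PredictionNode(-0.3), PredictionNode(0.3)
    root = PredictionNode(0.0, children=[
        SplitterNode(12, 0.5, lo1, hi1),
        SplitterNode(48, 1.5, lo3, hi3),
    ])
    lo1.children.append(SplitterNode(12, 1.5, lo2, hi2))
    model = ADTreeModel(root=root, iterations_used=3, item_order=[12, 48])
    distinct, mult = a.extract_items(model)
    assert distinct == {12, 48}
    assert mult == {12: 2, 48: 1}


def test_extract_items_root_only_empty():
    model = ADTreeModel(root=PredictionNode(0.2), iterations_used=0, item_order=[])
    assert a.extract_items(model) == (set(), {})


def test_planted_items_dominate_fitted_tree(default_matrix, default_model):
    """Early splits are all planted; planted items hold the majority overall."""
    planted = set(a.PUBLISHED_SUBSET)
    early = a.fit_adtree(default_matrix, TrainingConfig(iterations=6))
    early_distinct, _ = a.extract_items(early)
    assert early_distinct <= planted
    distinct, mult = a.extract_items(default_model)
    in_planted = sum(v for k, v in mult.items() if k in planted)
    assert in_planted > default_model.iterations_used / 2
    assert len(distinct & planted) >= 6


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def test_serialize_round_trip_root_only():
    model = ADTreeModel(root=PredictionNode(0.123456789012345), iterations_used=0,
                        item_order=[])
    back = a.deserialize_model(a.serialize_model(model))
    assert a.predict_score(back, {}) == a.predict_score(model, {})


def test_serialize_round_trip_fitted_model_exact(default_matrix, default_model):
    back = a.deserialize_model(a.serialize_model(default_model))
    rng = np.random.default_rng(4)
    idx = rng.integers(0, default_matrix.n_subjects, size=100)
    for i in idx:
        x = default_matrix.row_mapping(int(i))
        assert a.predict_score(back, x) == a.predict_score(default_model, x)


def test_deserialize_truncated_text_errors():
    text = a.serialize_model(hand_built_tree())
    with pytest.raises(ModelFormatError):
        a.deserialize_model(text[: len(text) // 2])


def test_deserialize_nonfinite_value_errors_with_path():
    text = a.serialize_model(hand_built_tree()).replace("-2.0", "NaN")
    with pytest.raises(ModelFormatError, match="root/splitters"):
        a.deserialize_model(text)


def test_deserialize_missing_child_errors():
    with pytest.raises(ModelFormatError, match="missing child"):
        a.deserialize_model(
            '{"model_type": "adtree", "iterations_used": 1, '
            '"root": {"value": 0.0, "splitters": [{"item_id": 1, '
            '"threshold": 0.5, "low": {"value": 0.1}}]}}'
        )
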