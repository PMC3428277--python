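"""Simple comparison learners sharing the ADTree's fit/predict contract.

DecisionStump: a single-level decision tree — one (item, threshold) test
with a class label on each side.  OneR: picks the single item whose
value→majority-label rule makes the fewest training errors.  Both emit a
constant confidence of 1 (scores ±1) so the evaluation machinery treats
every classifier uniformly; neither has tunable hyper-parameters here.

Tie rules: equal training error breaks to the lowest item id, then the
lowest threshold; a tied majority at a single score value resolves to
autism (−1) — in a screening instrument a false negative is costlier than
a false positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .instrument import RecodedMatrix, ValidationError
from .adtree import ModelFormatError

FORMAT_VERSION = 1


def _majority(n_pos: int, n_neg: int) -> int:
    """Majority label; ties resolve to autism (−1)."""
    return 1 if n_pos > n_neg else -1


# ---------------------------------------------------------------------------
# Decision stump
# ---------------------------------------------------------------------------


@dataclass
class StumpModel:
    """Single-split classifier.  ``item_id is None`` encodes a constant
    (majority-class) stump."""

    item_id: int | None
    threshold: float | None
    label_low: int
    label_high: int
    metadata: dict = field(default_factory=dict)

    def predict_row(self, x) -> int:
        if self.item_id is None:
            return self.label_high
        if self.item_id not in x:
            raise ValidationError(f"input is missing item {self.item_id}")
        return self.label_low if x[self.item_id] < self.threshold else self.label_high


def fit_stump(matrix: RecodedMatrix) -> StumpModel:
    """Exhaustive search over (item, threshold, side labels) minimising
    training misclassifications."""
    y = np.asarray(matrix.labels)
    n = y.size
    if n == 0:
        raise ValidationError("cannot fit on an empty matrix")
    n_pos = int((y > 0).sum())
    n_neg = n - n_pos
    maj = _majority(n_pos, n_neg)
    best_err = min(n_pos, n_neg)  # constant majority stump
    best: StumpModel = StumpModel(item_id=None, threshold=None,
                                  label_low=maj, label_high=maj)
    for j, item_id in enumerate(matrix.item_ids):
        col = matrix.scores[:, j]
        vals = np.unique(col)
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (float(lo) + float(hi)) / 2.0
            low = col < thr
            pos_low = int((y[low] > 0).sum())
            neg_low = int(low.sum()) - pos_low
            pos_high = n_pos - pos_low
            neg_high = n_neg - neg_low
            lab_low = _majority(pos_low, neg_low)
            lab_high = _majority(pos_high, neg_high)
            err = (pos_low if lab_low < 0 else neg_low) + (
                pos_high if lab_high < 0 else neg_high
            )
            if err < best_err:
                best_err = err
                best = StumpModel(item_id=item_id, threshold=thr,
                                  label_low=lab_low, label_high=lab_high)
    best.metadata["training_errors"] = best_err
    return best


# ---------------------------------------------------------------------------
# OneR
# ---------------------------------------------------------------------------


@dataclass
class OneRModel:
    """One-attribute rule: score value → label, with a default for values
    unseen in training (the overall training majority)."""

    item_id: int
    value_labels: dict[int, int]
    default_label: int
    metadata: dict = field(default_factory=dict)

    def predict_row(self, x) -> int:
        if self.item_id not in x:
            raise ValidationError(f"input is missing item {self.item_id}")
        return self.value_labels.get(int(x[self.item_id]), self.default_label)


def fit_oner(matrix: RecodedMatrix) -> OneRModel:
    y = np.asarray(matrix.labels)
    if y.size == 0:
        raise ValidationError("cannot fit on an empty matrix")
    default = _majority(int((y > 0).sum()), int((y < 0).sum()))
    best_err = None
    best = None
    for j, item_id in enumerate(matrix.item_ids):
        col = matrix.scores[:, j]
        value_labels: dict[int, int] = {}
        err = 0
        for v in np.unique(col):
            sel = col == v
            pos = int((y[sel] > 0).sum())
            neg = int(sel.sum()) - pos
            lab = _majority(pos, neg)
            value_labels[int(v)] = lab
            err += pos if lab < 0 else neg
        if best_err is None or err < best_err:
            best_err = err
            best = OneRModel(item_id=item_id, value_labels=value_labels,
                             default_label=default,
                             metadata={"training_errors": err})
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Shared learner contract + serialization
# ---------------------------------------------------------------------------


def _scores_from_rows(model, matrix: RecodedMatrix) -> np.ndarray:
    return np.array(
        [float(model.predict_row(matrix.row_mapping(i))) for i in range(matrix.n_subjects)]
    )


class StumpLearner:
    name = "DecisionStump"

    def fit(self, matrix: RecodedMatrix) -> StumpModel:
        return fit_stump(matrix)

    @staticmethod
    def scores(model: StumpModel, matrix: RecodedMatrix) -> np.ndarray:
        return _scores_from_rows(model, matrix)


class OneRLearner:
    name = "OneR"

    def fit(self, matrix: RecodedMatrix) -> OneRModel:
        return fit_oner(matrix)

    @staticmethod
    def scores(model: OneRModel, matrix: RecodedMatrix) -> np.ndarray:
        return _scores_from_rows(model, matrix)


def serialize_baseline(model) -> str:
    """Same structured-text container as the ADTree model file, with a
    ``model_type`` tag distinguishing the baselines."""
    if isinstance(model, StumpModel):
        doc = {
            "format_version": FORMAT_VERSION,
            "model_type": "decision_stump",
            "item_id": model.item_id,
            "threshold": model.threshold,
            "label_low": model.label_low,
            "label_high": model.label_high,
            "metadata": model.metadata,
        }
    elif isinstance(model, OneRModel):
        doc = {
            "format_version": FORMAT_VERSION,
            "model_type": "oner",
            "item_id": model.item_id,
            "value_labels": {str(k): v for k, v in model.value_labels.items()},
            "default_label": model.default_label,
            "metadata": model.metadata,
        }
    else:
        raise TypeError(f"not a baseline model: {type(model)!r}")
    return json.dumps(doc, indent=2)


def deserialize_baseline(text: str):
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"unparseable model text: {exc}") from exc
    kind = doc.get("model_type")
    try:
        if kind == "decision_stump":
            return StumpModel(
                item_id=doc["item_id"],
                threshold=doc["threshold"],
                label_low=int(doc["label_low"]),
                label_high=int(doc["label_high"]),
                metadata=doc.get("metadata", {}),
            )
        if kind == "oner":
            return OneRModel(
                item_id=int(doc["item_id"]),
                value_labels={int(k): int(v) for k, v in doc["value_labels"].items()},
                default_label=int(doc["default_label"]),
                metadata=doc.get("metadata", {}),
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed {kind} model: {exc}") from exc
    raise ModelFormatError(f"unknown model_type {kind!r}")
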