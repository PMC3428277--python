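"""Alternating decision tree (ADTree) learner, from scratch.

An ADTree alternates *prediction nodes*, each carrying a real additive
contribution, with *splitter nodes*, each testing one item against a
threshold.  A sheet's score is the sum of the contributions of every
prediction node it reaches: the root always, and a splitter's child
whenever the splitter's parent prediction node is reached and the
condition holds.  Multiple parallel splitters under one prediction node
all contribute, which is what distinguishes the model from a plain
decision tree.

The learner is the standard real-valued boosting construction: record
weights start at 1; the root contribution is ½·ln((W₊+ε)/(W₋+ε)) over all
records; each boosting round exhaustively searches every existing
prediction node (precondition c₁) × every (item, threshold) base condition
c₂ and adds the splitter minimising

    Z(c₁,c₂) = 2·[√(W₊(c₁∧c₂)·W₋(c₁∧c₂)) + √(W₊(c₁∧¬c₂)·W₋(c₁∧¬c₂))]
               + W(¬c₁)

with child contributions ½·ln((W₊+ε)/(W₋+ε)) on their partitions, after
which wᵢ ← wᵢ·exp(−yᵢ·rₜ(xᵢ)) for the newly added rule rₜ.  With labels
y ∈ {−1 autism, +1 non-spectrum}, a negative score classifies autism and
|score| measures confidence.

Candidate thresholds are midpoints between consecutive observed score
values of an item among the records reaching the precondition.  Ties in Z
break to the lowest item id, then the lowest threshold, then the earliest
created prediction node, making training deterministic and invariant to
record order.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .instrument import AUTISM, NON_SPECTRUM, RecodedMatrix, ValidationError

FORMAT_VERSION = 1

#: Relative slack under which two Z values are considered tied (guards the
#: deterministic tie-break against float summation noise).
_Z_TIE_RTOL = 1e-9


class ModelFormatError(ValueError):
    """Raised when a serialized model cannot be parsed or is implausible."""


# ---------------------------------------------------------------------------
# Model structure
# ---------------------------------------------------------------------------


@dataclass
class SplitterNode:
    item_id: int
    threshold: float
    low_child: "PredictionNode"   # reached when score < threshold
    high_child: "PredictionNode"  # reached when score >= threshold


@dataclass
class PredictionNode:
    value: float
    children: list[SplitterNode] = field(default_factory=list)


@dataclass
class ADTreeModel:
    root: PredictionNode
    iterations_used: int
    item_order: list[int]
    metadata: dict = field(default_factory=dict)
    #: Exponential loss Σᵢ exp(−yᵢ F(xᵢ)) after the root and after each
    #: boosting round (length iterations_used + 1).
    loss_trace: list[float] = field(default_factory=list)

    def splitters(self) -> list[SplitterNode]:
        out: list[SplitterNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            for sp in node.children:
                out.append(sp)
                stack.extend([sp.low_child, sp.high_child])
        return out


@dataclass(frozen=True)
class TrainingConfig:
    """Boosting hyper-parameters.

    ``iterations`` bounds the number of splitter nodes (10 matches the
    common default and keeps models in the shortened-questionnaire regime);
    ``epsilon`` smooths every ½·ln ratio against empty partitions.
    """

    iterations: int = 10
    epsilon: float = 1.0
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _half_log_ratio(w_pos: float, w_neg: float, eps: float) -> float:
    return 0.5 * math.log((w_pos + eps) / (w_neg + eps))


def fit_adtree(matrix: RecodedMatrix, config: TrainingConfig = TrainingConfig()) -> ADTreeModel:
    """Boost an alternating decision tree on a recoded cohort.

    A single-class cohort yields a warning and a root-only model.  Boosting
    stops early when no prediction node has a splittable item left.
    """
    X = np.asarray(matrix.scores, dtype=np.int8)
    y = np.asarray(matrix.labels, dtype=np.float64)
    n, n_items = X.shape
    if n == 0:
        raise ValidationError("cannot fit on an empty matrix")

    eps = config.epsilon
    w = np.ones(n)
    pos = y > 0
    neg = ~pos

    root_value = _half_log_ratio(w[pos].sum(), w[neg].sum(), eps)
    root = PredictionNode(value=root_value)
    w *= np.exp(-y * root_value)

    model = ADTreeModel(
        root=root,
        iterations_used=0,
        item_order=list(matrix.item_ids),
        metadata={
            "n_records": int(n),
            "epsilon": eps,
            "iterations_requested": config.iterations,
            "seed": config.random_seed,
        },
        loss_trace=[float(w.sum())],
    )

    single_class = not (pos.any() and neg.any())
    if single_class and config.iterations > 0:
        warnings.warn(
            "single-class training set: returning a root-only model",
            stacklevel=2,
        )
        return model

    # Prediction nodes in creation order, each with its reach mask.
    nodes: list[tuple[PredictionNode, np.ndarray]] = [(root, np.ones(n, dtype=bool))]
    total_items = np.arange(n_items)

    for _ in range(config.iterations):
        total_w = w.sum()
        best = None  # (Z, item_idx, threshold, node_idx, masks+weights)
        for node_idx, (_, reach) in enumerate(nodes):
            if not reach.any():
                continue
            w_out = total_w - w[reach].sum()
            Xr = X[reach]
            wp_r = np.where(pos[reach], w[reach], 0.0)
            wn_r = np.where(neg[reach], w[reach], 0.0)
            for item_idx in total_items:
                col = Xr[:, item_idx]
                vals = np.unique(col)
                if vals.size < 2:
                    continue
                for lo, hi in zip(vals[:-1], vals[1:]):
                    thr = (float(lo) + float(hi)) / 2.0
                    low = col < thr
                    wpl = wp_r[low].sum()
                    wnl = wn_r[low].sum()
                    wph = wp_r[~low].sum()
                    wnh = wn_r[~low].sum()
                    z = 2.0 * (math.sqrt(wpl * wnl) + math.sqrt(wph * wnh)) + w_out
                    cand = (z, int(matrix.item_ids[item_idx]), thr, node_idx,
                            item_idx, wpl, wnl, wph, wnh)
                    if best is None:
                        best = cand
                    else:
                        zb = best[0]
                        tol = _Z_TIE_RTOL * max(1.0, abs(zb), abs(z))
                        if z < zb - tol:
                            best = cand
                        elif abs(z - zb) <= tol and cand[1:4] < best[1:4]:
                            best = cand
        if best is None:
            break  # nothing splittable anywhere

        _, item_id, thr, node_idx, item_idx, wpl, wnl, wph, wnh = best
        parent, reach = nodes[node_idx]
        low_val = _half_log_ratio(wpl, wnl, eps)
        high_val = _half_log_ratio(wph, wnh, eps)
        low_mask = reach & (X[:, item_idx] < thr)
        high_mask = reach & ~ (X[:, item_idx] < thr)
        low_child = PredictionNode(value=low_val)
        high_child = PredictionNode(value=high_val)
        parent.children.append(
            SplitterNode(item_id=item_id, threshold=thr,
                         low_child=low_child, high_child=high_child)
        )
        w[low_mask] *= np.exp(-y[low_mask] * low_val)
        w[high_mask] *= np.exp(-y[high_mask] * high_val)
        nodes.append((low_child, low_mask))
        nodes.append((high_child, high_mask))
        model.iterations_used += 1
        model.loss_trace.append(float(w.sum()))

    return model


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def predict_score(model: ADTreeModel, x: Mapping[int, int]) -> float:
    """Sum the contributions of every prediction node reached by ``x``."""

    def visit(node: PredictionNode) -> float:
        total = node.value
        for sp in node.children:
            if sp.item_id not in x:
                raise ValidationError(f"input is missing item {sp.item_id}")
            child = sp.low_child if x[sp.item_id] < sp.threshold else sp.high_child
            total += visit(child)
        return total

    return visit(model.root)


def score_matrix(model: ADTreeModel, matrix: RecodedMatrix) -> np.ndarray:
    """Vectorised :func:`predict_score` over a recoded matrix."""
    cols = {i: matrix.scores[:, j].astype(np.float64) for j, i in enumerate(matrix.item_ids)}
    n = matrix.n_subjects
    out = np.zeros(n)

    def visit(node: PredictionNode, reach: np.ndarray) -> None:
        out[reach] += node.value
        for sp in node.children:
            if sp.item_id not in cols:
                raise ValidationError(f"matrix is missing item {sp.item_id}")
            low = cols[sp.item_id] < sp.threshold
            visit(sp.low_child, reach & low)
            visit(sp.high_child, reach & ~low)

    visit(model.root, np.ones(n, dtype=bool))
    return out


def classify_score(score: float, low_confidence_band: float = 0.5) -> tuple[str, float, bool]:
    """(label, confidence, low-confidence flag) from a signed score.

    Negative scores classify autism, non-negative non-spectrum; |score| is
    the confidence; the flag marks |score| below the band (a score of
    exactly 0 is always flagged).
    """
    if not math.isfinite(score):
        raise ValidationError(f"non-finite score {score!r}")
    if low_confidence_band < 0:
        raise ValueError("low_confidence_band must be >= 0")
    label = AUTISM if score < 0 else NON_SPECTRUM
    confidence = abs(score)
    flagged = confidence < low_confidence_band or score == 0
    return label, confidence, flagged


def extract_items(model: ADTreeModel) -> tuple[set[int], dict[int, int]]:
    """Distinct item ids used by the model's splitters, with multiplicity."""
    counts = Counter(sp.item_id for sp in model.splitters())
    return set(counts), dict(counts)


# ---------------------------------------------------------------------------
# Serialization (structured text, bit-exact float round trip)
# ---------------------------------------------------------------------------


def _node_to_dict(node: PredictionNode) -> dict:
    return {
        "value": node.value,
        "splitters": [
            {
                "item_id": sp.item_id,
                "threshold": sp.threshold,
                "low": _node_to_dict(sp.low_child),
                "high": _node_to_dict(sp.high_child),
            }
            for sp in node.children
        ],
    }


def serialize_model(model: ADTreeModel) -> str:
    """Human-readable structured text for a fitted model.

    JSON with ``repr``-precision floats, so deserialisation reproduces
    scores bit-exactly.
    """
    doc = {
        "format_version": FORMAT_VERSION,
        "model_type": "adtree",
        "iterations_used": model.iterations_used,
        "item_order": model.item_order,
        "metadata": model.metadata,
        "loss_trace": model.loss_trace,
        "root": _node_to_dict(model.root),
    }
    return json.dumps(doc, indent=2)


def _node_from_dict(d, path: str) -> PredictionNode:
    if not isinstance(d, dict):
        raise ModelFormatError(f"{path}: expected an object")
    try:
        value = float(d["value"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: missing or non-numeric value") from exc
    if not math.isfinite(value):
        raise ModelFormatError(f"{path}: non-finite value {value!r}")
    node = PredictionNode(value=value)
    for k, sp in enumerate(d.get("splitters", [])):
        sp_path = f"{path}/splitters[{k}]"
        if not isinstance(sp, dict) or "low" not in sp or "high" not in sp:
            raise ModelFormatError(f"{sp_path}: missing child")
        try:
            item_id = int(sp["item_id"])
            threshold = float(sp["threshold"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelFormatError(f"{sp_path}: malformed splitter") from exc
        if not math.isfinite(threshold):
            raise ModelFormatError(f"{sp_path}: non-finite threshold")
        node.children.append(
            SplitterNode(
                item_id=item_id,
                threshold=threshold,
                low_child=_node_from_dict(sp["low"], sp_path + "/low"),
                high_child=_node_from_dict(sp["high"], sp_path + "/high"),
            )
        )
    return node


def deserialize_model(text: str) -> ADTreeModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"unparseable model text: {exc}") from exc
    if not isinstance(doc, dict) or "root" not in doc:
        raise ModelFormatError("model document has no root node")
    if doc.get("model_type", "adtree") != "adtree":
        raise ModelFormatError(f"not an adtree model: {doc.get('model_type')!r}")
    root = _node_from_dict(doc["root"], "root")
    model = ADTreeModel(
        root=root,
        iterations_used=int(doc.get("iterations_used", 0)),
        item_order=[int(i) for i in doc.get("item_order", [])],
        metadata=doc.get("metadata", {}),
        loss_trace=[float(v) for v in doc.get("loss_trace", [])],
    )
    n_split = len(model.splitters())
    if n_split != model.iterations_used:
        raise ModelFormatError(
            f"iterations_used={model.iterations_used} but {n_split} splitters present"
        )
    return model


class ADTreeLearner:
    """fit/predict wrapper giving the ADTree the shared learner contract."""

    name = "ADTree"

    def __init__(self, config: TrainingConfig = TrainingConfig()):
        self.config = config

    def fit(self, matrix: RecodedMatrix) -> ADTreeModel:
        return fit_adtree(matrix, self.config)

    @staticmethod
    def scores(model: ADTreeModel, matrix: RecodedMatrix) -> np.ndarray:
        return score_matrix(model, matrix)
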