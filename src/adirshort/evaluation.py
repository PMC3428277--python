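"""Cross-validation, confusion metrics, classifier comparison and
score-vs-age profiling.

The positive class throughout is autism (label −1): TPR is sensitivity to
an autism diagnosis, FPR the fraction of non-spectrum controls flagged as
autism.  Undefined metrics (zero denominator) are reported as ``None`` and
rendered "NA", never coerced to 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .instrument import (
    AUTISM,
    LABEL_AUTISM,
    NON_SPECTRUM,
    RecodedMatrix,
    ValidationError,
)
from .adtree import classify_score


# ---------------------------------------------------------------------------
# Confusion counts and derived metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """FPR/TPR/specificity/accuracy; ``None`` marks an undefined ratio."""

    fpr: float | None
    tpr: float | None
    specificity: float | None
    accuracy: float | None
    table: ConfusionTable


def confusion_table(truth, predicted) -> ConfusionTable:
    """Cross-tabulate ±1 label vectors with autism (−1) as positive."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0:
        raise ValidationError("empty label vectors")
    if truth.shape != predicted.shape:
        raise ValidationError("truth and prediction lengths differ")
    for arr, name in ((truth, "truth"), (predicted, "predicted")):
        if not np.isin(arr, (-1, 1)).all():
            raise ValidationError(f"{name} labels must lie in {{-1,+1}}")
    pos = truth == LABEL_AUTISM
    pred_pos = predicted == LABEL_AUTISM
    return ConfusionTable(
        tp=int((pos & pred_pos).sum()),
        fn=int((pos & ~pred_pos).sum()),
        fp=int((~pos & pred_pos).sum()),
        tn=int((~pos & ~pred_pos).sum()),
    )


def metrics(ct: ConfusionTable) -> MetricsReport:
    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    fpr = ratio(ct.fp, ct.fp + ct.tn)
    return MetricsReport(
        fpr=fpr,
        tpr=ratio(ct.tp, ct.tp + ct.fn),
        specificity=None if fpr is None else 1.0 - fpr,
        accuracy=ratio(ct.tp + ct.tn, ct.total),
        table=ct,
    )


def format_ratio(value: float | None, decimals: int = 3) -> str:
    """Presentation rounding for rates, e.g. 1/75 → ``"0.013"``."""
    return "NA" if value is None else f"{value:.{decimals}f}"


def format_percent(value: float | None, decimals: int = 2) -> str:
    """Presentation rounding for percentages, e.g. 965/966 → ``"99.90%"``."""
    return "NA" if value is None else f"{100.0 * value:.{decimals}f}%"


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    scores: np.ndarray            # pooled out-of-fold signed scores
    predictions: np.ndarray       # pooled out-of-fold ±1 labels
    fold_assignment: np.ndarray   # test-fold index per record
    models: list = field(default_factory=list)
    report: MetricsReport | None = None


def kfold_cv(matrix: RecodedMatrix, learner, k: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation of a learner.

    Folds are stratified by class (with the heavy case/control imbalance an
    unstratified split can leave folds control-free, corrupting FPR) and
    shuffled under ``seed``.  Each record is scored exactly once by a model
    not trained on it.  If either class has fewer than ``k`` members the
    split falls back to unstratified with a warning.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    y = np.asarray(matrix.labels)
    n = y.size
    if n < k:
        raise ValidationError(f"cannot split {n} records into {k} folds")
    class_counts = np.unique(y, return_counts=True)[1]
    if class_counts.min() < k or class_counts.size < 2:
        warnings.warn(
            f"a class has fewer than k={k} members: using unstratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), y)

    scores = np.full(n, np.nan)
    folds = np.full(n, -1)
    models = []
    for fold_idx, (train_idx, test_idx) in enumerate(split):
        model = learner.fit(matrix.subset(train_idx))
        models.append(model)
        scores[test_idx] = learner.scores(model, matrix.subset(test_idx))
        folds[test_idx] = fold_idx
    assert not np.isnan(scores).any()
    predictions = np.where(scores < 0, LABEL_AUTISM, -LABEL_AUTISM).astype(np.int8)
    report = metrics(confusion_table(y, predictions))
    return CVResult(
        scores=scores,
        predictions=predictions,
        fold_assignment=folds,
        models=models,
        report=report,
    )


# ---------------------------------------------------------------------------
# Classifier comparison (1-specificity vs sensitivity)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonRow:
    classifier: str
    fpr: float | None
    tpr: float | None
    accuracy: float | None


def compare_classifiers(
    matrix: RecodedMatrix,
    learners,
    external_rows: list[ComparisonRow] | None = None,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """One cross-validated row per learner, plus externally computed rows
    appended verbatim.  The (FPR, TPR) columns double as the coordinates of
    the 1-specificity vs sensitivity comparison plot."""
    external_rows = external_rows or []
    if not learners and not external_rows:
        raise ValidationError("nothing to compare")
    rows = []
    for learner in learners:
        res = kfold_cv(matrix, learner, k=k, seed=seed)
        rep = res.report
        rows.append(ComparisonRow(learner.name, rep.fpr, rep.tpr, rep.accuracy))
    rows.extend(external_rows)
    return pd.DataFrame(
        {
            "classifier": [r.classifier for r in rows],
            "FPR": [r.fpr for r in rows],
            "TPR": [r.tpr for r in rows],
            "accuracy": [r.accuracy for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# Score-vs-age profile
# ---------------------------------------------------------------------------


def score_profile(
    model,
    matrix: RecodedMatrix,
    scores: np.ndarray | None = None,
    low_confidence_band: float = 0.5,
    scorer=None,
) -> pd.DataFrame:
    """Per-subject signed score against age, for the score-age scatter.

    ``scorer(model, matrix)`` defaults to the ADTree scorer; pass the
    pooled CV scores via ``scores`` to profile out-of-fold predictions.
    """
    if matrix.ages_months is None:
        raise ValidationError("matrix carries no ages")
    if scores is None:
        if scorer is None:
            from .adtree import score_matrix as scorer  # noqa: PLC0415
        scores = scorer(model, matrix)
    records = []
    for i, sid in enumerate(matrix.subject_ids):
        label, confidence, flagged = classify_score(float(scores[i]), low_confidence_band)
        records.append(
            {
                "subject_id": sid,
                "age_years": matrix.ages_months[i] / 12.0,
                "score": float(scores[i]),
                "true_label": AUTISM if matrix.labels[i] == LABEL_AUTISM else NON_SPECTRUM,
                "predicted_label": label,
                "confidence": confidence,
                "low_confidence": flagged,
            }
        )
    return pd.DataFrame(records)
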