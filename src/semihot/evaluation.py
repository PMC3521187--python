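"""Classification metrics, ROC/AUC and the cross-validation protocols.

Two evaluation protocols are provided for the semi-supervised setting:

* stratified k-fold cross-validation in which the held-out fold's features
  enter training as the unlabeled pool (transductive use) and predictions
  are pooled over folds before scoring;
* the "random-20" protocol: repeatedly draw 20 labeled samples, use the
  rest as both unlabeled pool and test set, and average the metrics.

Trainers are callables ``trainer(X_l, y_l, X_u, seed) -> score_fn`` where
``score_fn(X)`` returns real scores (label = sign).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .model import HotspotSemiBoost
from .semiboost import SampleSet, default_base_learner

logger = logging.getLogger(__name__)

Trainer = Callable[[np.ndarray, np.ndarray, np.ndarray, int], Callable[[np.ndarray], np.ndarray]]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == -1) & (y_pred == 1)).sum()),
            tn=int(((y_true == -1) & (y_pred == -1)).sum()),
            fn=int(((y_true == 1) & (y_pred == -1)).sum()),
        )


@dataclass
class EvaluationReport:
    precision: float
    recall: float
    specificity: float
    accuracy: float
    f1: float
    counts: ConfusionCounts | None = None
    roc_points: np.ndarray | None = None  # (n, 2) of (fpr, tpr)
    auc: float | None = None
    per_fold: list["EvaluationReport"] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "precision": self.precision, "recall": self.recall,
            "specificity": self.specificity, "accuracy": self.accuracy,
            "f1": self.f1,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.counts is not None:
            d.update(tp=self.counts.tp, fp=self.counts.fp,
                     tn=self.counts.tn, fn=self.counts.fn)
        return d


def _ratio(num: float, den: float, label: str) -> float:
    if den == 0:
        logger.debug("%s: 0/0 encountered, reported as 0", label)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> EvaluationReport:
    """Precision, recall (sensitivity), specificity, accuracy and F1."""
    if c.n < 1:
        raise ValueError("cannot score an empty prediction set")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    accuracy = (c.tp + c.tn) / c.n
    f1 = _ratio(2.0 * precision * recall, precision + recall, "f1")
    return EvaluationReport(
        precision=precision, recall=recall, specificity=specificity,
        accuracy=accuracy, f1=f1, counts=c,
    )


def f1_score_from(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    return _ratio(2.0 * precision * recall, precision + recall, "f1")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr) over a threshold sweep and the trapezoid AUC.

    Tied scores are handled rank-averaged, so the AUC equals the
    Mann-Whitney pair-counting statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {-1, 1}:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


def supervised_svm_trainer(base_learner: Callable[[], object] = default_base_learner) -> Trainer:
    """Labeled-only baseline: fit the base SVM, ignore the unlabeled pool."""

    def train(X_l, y_l, X_u, seed):
        mean = X_l.mean(axis=0)
        scale = X_l.std(axis=0)
        scale[scale == 0] = 1.0
        clf = base_learner()
        if hasattr(clf, "random_state"):
            clf.random_state = seed
        clf.fit((X_l - mean) / scale, y_l)

        def score(X):
            Xs = (np.atleast_2d(X) - mean) / scale
            if isinstance(clf, SVC):
                return clf.decision_function(Xs)
            return clf.predict(Xs).astype(float)

        return score

    return train


def semiboost_trainer(
    sigma: float = 3.0,
    C: float | str = "auto",
    T: int = 20,
    threshold: float = 0.3,
    top_frac: float = 0.10,
    base_learner: Callable[[], object] = default_base_learner,
    confidence: str = "normalized",
) -> Trainer:
    """Semi-supervised trainer: the held-out features act as unlabeled pool."""

    def train(X_l, y_l, X_u, seed):
        X = np.vstack([X_l, X_u])
        y = np.concatenate([y_l, np.zeros(len(X_u), dtype=int)])
        model = HotspotSemiBoost(
            X, y, sigma=sigma, C=C, T=T, threshold=threshold,
            top_frac=top_frac, base_learner=base_learner, confidence=confidence,
        )
        res = model.fit(seed=seed)
        return res.predict_score

    return train


def _check_all_labeled(data: SampleSet) -> tuple[np.ndarray, np.ndarray]:
    if (data.y == 0).any():
        raise ValueError("cross-validation requires fully labeled data")
    return data.X, data.y


def kfold_cv(
    data: SampleSet,
    k: int,
    trainer: Trainer,
    seed: int = 0,
    pooled: bool = True,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with transductive unlabeled pools.

    Each fold's test features are passed to the trainer as the unlabeled
    pool.  With ``pooled=True`` (default) predictions are pooled over folds
    before computing the metrics; otherwise per-fold metrics are averaged.
    The pooled report always carries the per-fold breakdown and the pooled
    ROC/AUC.
    """
    X, y = _check_all_labeled(data)
    if k < 2:
        raise ValueError("k must be >= 2")
    class_counts = np.unique(y, return_counts=True)[1]
    if class_counts.min() < k:
        raise ValueError("every class needs at least k members for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=int)
    per_fold: list[EvaluationReport] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        score_fn = trainer(X[train_idx], y[train_idx], X[test_idx], seed + fold)
        s = np.asarray(score_fn(X[test_idx]), dtype=float)
        scores[test_idx] = s
        preds[test_idx] = np.where(s >= 0, 1, -1)
        per_fold.append(metrics(ConfusionCounts.from_predictions(y[test_idx], preds[test_idx])))
    if pooled:
        report = metrics(ConfusionCounts.from_predictions(y, preds))
    else:
        report = _average_reports(per_fold)
    report.per_fold = per_fold
    report.roc_points, report.auc = roc_auc(scores, y)
    return report


def _average_reports(reports: list[EvaluationReport]) -> EvaluationReport:
    def mean(attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in reports]))

    return EvaluationReport(
        precision=mean("precision"), recall=mean("recall"),
        specificity=mean("specificity"), accuracy=mean("accuracy"),
        f1=mean("f1"),
    )


def random20_test(
    data: SampleSet,
    trainer: Trainer,
    n_labeled: int = 20,
    repeats: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Average metrics over repeated tiny-training-set draws.

    Each repeat draws ``n_labeled`` samples (redrawn until both classes are
    present) to train on; the remaining samples serve as unlabeled pool and
    test set.  Metrics are averaged over the repeats; the per-repeat
    reports ride along in ``per_fold``.
    """
    X, y = _check_all_labeled(data)
    n = len(y)
    if n <= n_labeled:
        raise ValueError(f"need more than {n_labeled} samples")
    rng = np.random.default_rng(seed)
    reports: list[EvaluationReport] = []
    for rep in range(repeats):
        for attempt in range(100):
            idx = rng.choice(n, size=n_labeled, replace=False)
            if len(np.unique(y[idx])) == 2:
                break
            logger.info("repeat %d: single-class draw, redrawing", rep)
        else:
            raise RuntimeError("could not draw a two-class training set")
        rest = np.setdiff1d(np.arange(n), idx)
        score_fn = trainer(X[idx], y[idx], X[rest], seed + rep)
        s = np.asarray(score_fn(X[rest]), dtype=float)
        preds = np.where(s >= 0, 1, -1)
        reports.append(metrics(ConfusionCounts.from_predictions(y[rest], preds)))
    out = _average_reports(reports)
    out.per_fold = reports
    return out
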