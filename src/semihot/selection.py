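"""Random-forest permutation importance and exhaustive subset search.

Feature ranking follows the Breiman recipe: fit a forest, then measure the
mean decrease in accuracy when each feature's values are permuted.  The
best-subset search exhaustively scores every combination of a short
candidate list (the top-ranked features) with a cross-validated F1
evaluator, preferring smaller subsets on ties.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

Evaluator = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class ImportanceReport:
    feature_names: list[str]
    importances: np.ndarray  # mean decrease in accuracy under permutation
    importances_std: np.ndarray

    def __post_init__(self) -> None:
        self.importances = np.asarray(self.importances, dtype=float)
        if not np.isfinite(self.importances).all():
            raise ValueError("importances must be finite")
        if len(self.feature_names) != len(self.importances):
            raise ValueError("names and importances must align")

    @property
    def ranking(self) -> list[str]:
        """Feature names by decreasing importance; ties broken by name."""
        order = sorted(
            range(len(self.feature_names)),
            key=lambda i: (-self.importances[i], self.feature_names[i]),
        )
        return [self.feature_names[i] for i in order]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.importances.tolist()))


def rf_importance(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    n_trees: int = 500,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Permutation importance from a random forest.

    Deterministic given ``seed``; constant features simply score 0.
    Requires fully labeled two-class data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if (y == 0).any():
        raise ValueError("unlabeled rows are not allowed in feature selection")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    perm = permutation_importance(
        forest, X, y, scoring="accuracy", n_repeats=n_repeats, random_state=seed
    )
    return ImportanceReport(
        feature_names=list(feature_names),
        importances=perm.importances_mean,
        importances_std=perm.importances_std,
    )


def select_top_k(report: ImportanceReport, k: int = 10) -> list[str]:
    """The k highest-importance feature names (ties broken by name order)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(report.feature_names):
        raise ValueError(f"k={k} exceeds the {len(report.feature_names)} features")
    top = report.ranking[:k]
    logger.debug("top-%d features: %s", k, top)
    return top


def cv_f1_evaluator(k: int = 5, seed: int = 0) -> Evaluator:
    """Mean F1 of a standardized RBF SVM under stratified k-fold CV."""

    def evaluate(X: np.ndarray, y: np.ndarray) -> float:
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return float(np.mean(cross_val_score(clf, X, y, cv=cv, scoring="f1")))

    return evaluate


def search_best_subset(
    X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[str],
    feature_names: Sequence[str],
    evaluator: Evaluator | None = None,
    max_size: int = 6,
    seed: int = 0,
) -> tuple[list[str], float]:
    """Exhaustive search over non-empty candidate subsets up to ``max_size``.

    Returns the subset with the highest evaluator score; ties prefer the
    smaller subset, then lexicographic order.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if len(candidates) > 12:
        raise ValueError("exhaustive search supports at most 12 candidates")
    X = np.asarray(X, dtype=float)
    name_to_col = {n: i for i, n in enumerate(feature_names)}
    missing = [c for c in candidates if c not in name_to_col]
    if missing:
        raise KeyError(f"candidates not in feature_names: {missing}")
    if evaluator is None:
        evaluator = cv_f1_evaluator(seed=seed)
    best: tuple[float, int, tuple[str, ...]] | None = None
    for size in range(1, min(max_size, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, size):
            cols = [name_to_col[c] for c in combo]
            score = evaluator(X[:, cols], y)
            key = (-score, size, tuple(sorted(combo)))
            if best is None or key < (-best[0], best[1], best[2]):
                best = (score, size, tuple(sorted(combo)))
    assert best is not None
    logger.info("best subset (score %.4f): %s", best[0], list(best[2]))
    return list(best[2]), best[0]
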