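"""Semi-supervised boosting with similarity-graph confidences.

The algorithm wraps a supervised base classifier (an RBF-kernel SVM by
default) in a boosting loop that exploits unlabeled data.  A Gaussian
similarity graph connects unlabeled points to labeled points (S_ul) and to
each other (S_uu).  At every iteration each unlabeled point i receives a
positive-class confidence p_i and a negative-class confidence q_i:

    p_i = phi * sum_j  S^ul_ij e^{-2 H_i} [y_j = +1]
        + psi * sum_j  S^uu_ij e^{H_j - H_i}
    q_i = phi * sum_j  S^ul_ij e^{+2 H_i} [y_j = -1]
        + psi * sum_j  S^uu_ij e^{H_i - H_j}

(the labeled-compatibility weight attaches to the unlabeled point's own
ensemble score H_i, signed by the neighbour's class, as the boosting
objective's exponent exp(-2 y_j (H_i + alpha h_i)) dictates — so the
formulas swap p and q when all labels and scores flip sign)

where H is the current ensemble score, phi = 1/(1 + C/2),
psi = (C/2)/(1 + C/2), and — in the default "normalized" variant — each
similarity row is divided by its sum so that p_i, q_i are bounded by 1.
Confidently classified points (|p_i - q_i| >= tau, restricted to the top
fraction) are pseudo-labeled with sign(p_i - q_i) and added to the training
set of the next base classifier h_t, which joins the ensemble with weight

    alpha_t = 1/4 ln [ (sum p_i [h_i=+1] + sum q_i [h_i=-1]) /
                       (sum p_i [h_i=-1] + sum q_i [h_i=+1]) ].

Training stops after T rounds or as soon as alpha drops below zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: Cap applied to alpha when the disagreement mass vanishes.
ALPHA_CAP = 50.0


# ---------------------------------------------------------------------------
# data containers


@dataclass
class SampleSet:
    """Feature matrix with labels in {+1, -1, 0}; 0 marks unlabeled rows."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError("X must be a 2-D matrix with at least one feature")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        if not np.isin(self.y, (-1, 0, 1)).all():
            raise ValueError("labels must lie in {+1, -1, 0}")
        if (self.y != 0).sum() < 1:
            raise ValueError("at least one labeled row is required")
        if self.feature_names is not None and len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        feature_cols: Sequence[str] | None = None,
    ) -> "SampleSet":
        if feature_cols is None:
            feature_cols = [
                c for c in df.columns
                if c != label_col and pd.api.types.is_numeric_dtype(df[c])
            ]
        X = df[list(feature_cols)].to_numpy(dtype=float)
        y = df[label_col].fillna(0).to_numpy(dtype=int)
        return cls(X=X, y=y, feature_names=list(feature_cols))

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.y != 0

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())

    @property
    def n_unlabeled(self) -> int:
        return int((~self.labeled_mask).sum())

    @property
    def X_labeled(self) -> np.ndarray:
        return self.X[self.labeled_mask]

    @property
    def y_labeled(self) -> np.ndarray:
        return self.y[self.labeled_mask]

    @property
    def X_unlabeled(self) -> np.ndarray:
        return self.X[~self.labeled_mask]


def rbf_similarity(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian similarity S_ij = exp(-||a_i - b_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    return rbf_kernel(A, B, gamma=1.0 / (2.0 * sigma**2))


@dataclass
class SimilarityGraph:
    """Unlabeled-to-labeled and unlabeled-to-unlabeled Gaussian similarities."""

    S_ul: np.ndarray
    S_uu: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.S_ul = np.asarray(self.S_ul, dtype=float)
        self.S_uu = np.asarray(self.S_uu, dtype=float)
        n_u = self.S_ul.shape[0]
        if self.S_uu.shape != (n_u, n_u):
            raise ValueError("S_uu must be square with the S_ul row count")
        if not np.allclose(self.S_uu, self.S_uu.T):
            raise ValueError("S_uu must be symmetric")

    @classmethod
    def build(cls, X_labeled: np.ndarray, X_unlabeled: np.ndarray, sigma: float) -> "SimilarityGraph":
        return cls(
            S_ul=rbf_similarity(X_unlabeled, X_labeled, sigma),
            S_uu=rbf_similarity(X_unlabeled, X_unlabeled, sigma),
            sigma=sigma,
        )

    def row_normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """Each row of S_ul and S_uu divided by its own sum."""
        rs_ul = self.S_ul.sum(axis=1, keepdims=True)
        rs_uu = self.S_uu.sum(axis=1, keepdims=True)
        if (rs_ul == 0).any() or (rs_uu == 0).any():
            raise ValueError("zero similarity row sum; cannot normalize")
        return self.S_ul / rs_ul, self.S_uu / rs_uu


@dataclass
class Confidences:
    """Class confidences for the unlabeled points."""

    p: np.ndarray
    q: np.ndarray
    C: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.p.shape != self.q.shape:
            raise ValueError("p and q must have the same shape")

    @property
    def margin(self) -> np.ndarray:
        return self.p - self.q


def _phi_psi(C: float) -> tuple[float, float]:
    phi = 1.0 / (1.0 + C / 2.0)
    psi = (C / 2.0) / (1.0 + C / 2.0)
    return phi, psi


def compute_confidences(
    graph: SimilarityGraph,
    y_l: np.ndarray,
    H_u: np.ndarray,
    H_l: np.ndarray,
    C: float,
) -> Confidences:
    """Normalized-similarity confidences (the default variant).

    ``H_l`` is accepted for contract parity but does not enter the
    formulas: the boosting objective weights each unlabeled point by its
    own ensemble score (see the module docstring).
    """
    if C < 0:
        raise ValueError("C must be non-negative")
    y_l = np.asarray(y_l, dtype=int)
    H_u = np.asarray(H_u, dtype=float)
    H_l = np.asarray(H_l, dtype=float)
    S_ul, S_uu = graph.row_normalized()
    phi, psi = _phi_psi(C)
    e_pos, e_neg = np.exp(H_u), np.exp(-H_u)
    p_lab = np.exp(-2.0 * H_u) * (S_ul @ (y_l == 1).astype(float))
    q_lab = np.exp(2.0 * H_u) * (S_ul @ (y_l == -1).astype(float))
    # pairwise e^{H_j - H_i} = e^{H_j} * e^{-H_i}
    p_unl = e_neg * (S_uu @ e_pos)
    q_unl = e_pos * (S_uu @ e_neg)
    return Confidences(p=phi * p_lab + psi * p_unl, q=phi * q_lab + psi * q_unl, C=C)


def compute_confidences_original(
    graph: SimilarityGraph,
    y_l: np.ndarray,
    H_u: np.ndarray,
    H_l: np.ndarray,
    C: float,
) -> Confidences:
    """Unnormalized confidences with weights (1, C/2) — the original variant."""
    if C < 0:
        raise ValueError("C must be non-negative")
    y_l = np.asarray(y_l, dtype=int)
    H_u = np.asarray(H_u, dtype=float)
    H_l = np.asarray(H_l, dtype=float)
    p_lab = np.exp(-2.0 * H_u) * (graph.S_ul @ (y_l == 1).astype(float))
    q_lab = np.exp(2.0 * H_u) * (graph.S_ul @ (y_l == -1).astype(float))
    e_pos, e_neg = np.exp(H_u), np.exp(-H_u)
    p_unl = e_neg * (graph.S_uu @ e_pos)
    q_unl = e_pos * (graph.S_uu @ e_neg)
    half_C = C / 2.0
    return Confidences(p=p_lab + half_C * p_unl, q=q_lab + half_C * q_unl, C=C)


def sample_pseudolabeled(
    conf: Confidences,
    threshold: float = 0.3,
    top_frac: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Select confidently classified unlabeled points.

    Keeps points with |p - q| >= threshold and, of those, the
    ``ceil(top_frac * n_u)`` with the largest margins (ties broken by index
    order).  Returns (indices, pseudo-labels = sign(p - q)); zero margins
    are never selected.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    margin = conf.margin
    abs_margin = np.abs(margin)
    candidates = np.flatnonzero((abs_margin >= threshold) & (abs_margin > 0))
    if len(candidates) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    n_keep = int(np.ceil(top_frac * len(margin)))
    # stable sort descending on margin, ascending on index among ties
    order = np.lexsort((candidates, -abs_margin[candidates]))
    chosen = np.sort(candidates[order[:n_keep]])
    return chosen, np.sign(margin[chosen]).astype(int)


def compute_alpha(conf: Confidences, h_u: np.ndarray) -> float:
    """Ensemble weight from the agreement of base predictions with (p, q)."""
    h_u = np.asarray(h_u)
    if not np.isin(h_u, (-1, 1)).all():
        raise ValueError("base predictions must be in {-1, +1}")
    pos = h_u == 1
    numer = conf.p[pos].sum() + conf.q[~pos].sum()
    denom = conf.p[~pos].sum() + conf.q[pos].sum()
    if denom == 0.0:
        if numer == 0.0:
            return 0.0
        logger.info("alpha denominator is 0; capping alpha at %.1f", ALPHA_CAP)
        return ALPHA_CAP
    if numer == 0.0:
        return -ALPHA_CAP
    return float(0.25 * np.log(numer / denom))


# ---------------------------------------------------------------------------
# the boosting loop


def default_base_learner() -> SVC:
    """RBF-kernel SVM with library defaults — the standard base classifier."""
    return SVC(kernel="rbf")


@dataclass
class BoostStage:
    alpha: float
    classifier: object


@dataclass
class IterationRecord:
    t: int
    alpha: float
    n_pseudo: int
    n_pseudo_pos: int
    n_pseudo_neg: int
    appended: bool


@dataclass
class BoostEnsemble:
    """Weighted ensemble H(x) = sum_t alpha_t h_t(x) plus its preprocessing."""

    stages: list[BoostStage]
    sigma: float
    C: float
    T_max: int
    threshold: float
    top_frac: float
    feature_names: list[str] | None = None
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    history: list[IterationRecord] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([s.alpha for s in self.stages])

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_scale
        return X

    def decision_function(self, X: np.ndarray, pretransformed: bool = False) -> np.ndarray:
        """Real-valued ensemble score H(x)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.stages and X.shape[1] != _stage_dim(self.stages[0]):
            raise ValueError(
                f"X has {X.shape[1]} features, ensemble expects {_stage_dim(self.stages[0])}"
            )
        if X.shape[0] == 0:
            return np.zeros(0)
        if not pretransformed:
            X = self.transform(X)
        H = np.zeros(X.shape[0])
        for stage in self.stages:
            H += stage.alpha * stage.classifier.predict(X)
        return H

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels sign(H(x)); ties (H = 0) resolve to +1."""
        H = self.decision_function(X)
        return np.where(H >= 0, 1, -1)


def _stage_dim(stage: BoostStage) -> int:
    return int(stage.classifier.n_features_in_)


def predict_score(ensemble: BoostEnsemble, X: np.ndarray) -> np.ndarray:
    return ensemble.decision_function(X)


def fit_semiboost(
    data: SampleSet,
    base_learner: Callable[[], object] | object = default_base_learner,
    sigma: float = 3.0,
    C: float | str = "auto",
    T: int = 20,
    threshold: float = 0.3,
    top_frac: float = 0.10,
    seed: int = 0,
    confidence: str = "normalized",
    standardize: bool = True,
) -> BoostEnsemble:
    """Train the boosting ensemble on labeled + unlabeled data.

    ``C`` defaults to n_l / n_u ("auto").  The similarity graph is built
    once, on (optionally z-scored) features, before the iterations.  Every
    base classifier is trained on all labeled points plus the currently
    pseudo-labeled ones; a round whose alpha is negative stops the loop
    without being appended.
    """
    y_lab = data.y_labeled
    if data.n_labeled < 2 or len(np.unique(y_lab)) < 2:
        raise ValueError("need at least two labeled samples covering both classes")
    if data.n_unlabeled == 0:
        raise ValueError("semi-supervised training requires unlabeled rows")
    if T < 1:
        raise ValueError("T must be >= 1")
    conf_fn = {
        "normalized": compute_confidences,
        "original": compute_confidences_original,
    }.get(confidence)
    if conf_fn is None:
        raise ValueError(f"unknown confidence variant {confidence!r}")
    C_val = data.n_labeled / data.n_unlabeled if C == "auto" else float(C)
    rng = np.random.default_rng(seed)

    X = data.X
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = (X - mean) / scale
    else:
        mean = scale = None
        Xs = X
    X_l, X_u = Xs[data.labeled_mask], Xs[~data.labeled_mask]
    graph = SimilarityGraph.build(X_l, X_u, sigma)

    ensemble = BoostEnsemble(
        stages=[], sigma=sigma, C=C_val, T_max=T, threshold=threshold,
        top_frac=top_frac, feature_names=data.feature_names,
        scaler_mean=mean, scaler_scale=scale,
    )
    H_l = np.zeros(len(X_l))
    H_u = np.zeros(len(X_u))
    for t in range(1, T + 1):
        conf = conf_fn(graph, y_lab, H_u, H_l, C_val)
        idx, pseudo = sample_pseudolabeled(conf, threshold, top_frac)
        if len(idx) == 0:
            logger.info("iteration %d: empty pseudo-label set, training on labeled only", t)
            X_t, y_t = X_l, y_lab
        else:
            X_t = np.vstack([X_l, X_u[idx]])
            y_t = np.concatenate([y_lab, pseudo])
        if len(np.unique(y_t)) < 2:  # cannot happen with both-class labels, kept defensive
            X_t, y_t = X_l, y_lab
        learner = base_learner() if callable(base_learner) else clone(base_learner)
        if hasattr(learner, "random_state"):
            learner.random_state = int(rng.integers(0, 2**31 - 1))
        try:
            learner.fit(X_t, y_t)
        except Exception as exc:
            raise RuntimeError(f"base learner failed at iteration {t}: {exc}") from exc
        h_u = np.asarray(learner.predict(X_u))
        alpha = compute_alpha(conf, h_u)
        appended = alpha > 0
        ensemble.history.append(
            IterationRecord(
                t=t, alpha=alpha, n_pseudo=len(idx),
                n_pseudo_pos=int((pseudo == 1).sum()),
                n_pseudo_neg=int((pseudo == -1).sum()),
                appended=appended,
            )
        )
        if not appended:
            if ensemble.n_stages == 0:
                # graph and first classifier disagree; keep the supervised
                # stage with unit weight so the ensemble is never empty
                logger.warning(
                    "first-round alpha %.4f <= 0; retaining the supervised "
                    "classifier with weight 1", alpha,
                )
                ensemble.stages.append(BoostStage(alpha=1.0, classifier=learner))
            else:
                logger.info("iteration %d: alpha %.4f <= 0, stopping", t, alpha)
            break
        ensemble.stages.append(BoostStage(alpha=alpha, classifier=learner))
        H_l += alpha * np.asarray(learner.predict(X_l))
        H_u += alpha * h_u
    return ensemble
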