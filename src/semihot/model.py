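"""Model / Results interface over the boosting core.

:class:`HotspotSemiBoost` holds the data and hyper-parameters;
:meth:`HotspotSemiBoost.fit` runs the boosting loop and returns a
:class:`HotspotSemiBoostResults` carrying the trained ensemble, the
per-iteration diagnostics, prediction methods, a text ``summary()`` and
persistence helpers.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd

from .semiboost import (
    BoostEnsemble,
    SampleSet,
    default_base_learner,
    fit_semiboost,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class HotspotSemiBoost:
    """Semi-supervised boosting classifier for interface hot-spot residues.

    Parameters
    ----------
    X, y
        Feature matrix and labels in {+1 hot spot, -1 non-hot spot,
        0 unlabeled}; or pass a prepared :class:`SampleSet` as ``X``.
    sigma
        Scale of the Gaussian similarity graph (on standardized features).
    C
        Labeled/unlabeled trade-off; ``"auto"`` uses n_labeled/n_unlabeled.
    T, threshold, top_frac
        Maximum boosting rounds, the confidence-margin cut-off for
        pseudo-labeling, and the fraction of unlabeled points admitted per
        round.
    base_learner
        Zero-argument factory for the supervised base classifier
        (default: RBF-kernel SVM).
    confidence
        ``"normalized"`` (row-normalized similarities, bounded confidences)
        or ``"original"`` (unnormalized variant).
    """

    def __init__(
        self,
        X: np.ndarray | SampleSet,
        y: np.ndarray | None = None,
        sigma: float = 3.0,
        C: float | str = "auto",
        T: int = 20,
        threshold: float = 0.3,
        top_frac: float = 0.10,
        base_learner: Callable[[], object] = default_base_learner,
        confidence: str = "normalized",
        standardize: bool = True,
        feature_names: Sequence[str] | None = None,
    ) -> None:
        if isinstance(X, SampleSet):
            self.data = X
        else:
            if y is None:
                raise ValueError("y is required when X is a plain matrix")
            self.data = SampleSet(
                X=X, y=y,
                feature_names=list(feature_names) if feature_names is not None else None,
            )
        self.sigma = sigma
        self.C = C
        self.T = T
        self.threshold = threshold
        self.top_frac = top_frac
        self.base_learner = base_learner
        self.confidence = confidence
        self.standardize = standardize

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        feature_cols: Sequence[str] | None = None,
        **kwargs,
    ) -> "HotspotSemiBoost":
        """Build the model from a feature table with a {+1,-1,0} label column."""
        return cls(SampleSet.from_dataframe(df, label_col, feature_cols), **kwargs)

    def fit(self, seed: int = 0) -> "HotspotSemiBoostResults":
        ensemble = fit_semiboost(
            self.data,
            base_learner=self.base_learner,
            sigma=self.sigma,
            C=self.C,
            T=self.T,
            threshold=self.threshold,
            top_frac=self.top_frac,
            seed=seed,
            confidence=self.confidence,
            standardize=self.standardize,
        )
        return HotspotSemiBoostResults(self, ensemble, seed=seed)


class HotspotSemiBoostResults:
    """Fitted ensemble plus training diagnostics."""

    def __init__(self, model: HotspotSemiBoost | None, ensemble: BoostEnsemble, seed: int = 0):
        self.model = model
        self.ensemble = ensemble
        self.seed = seed

    # -- prediction ---------------------------------------------------------

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Real-valued ensemble score H(x) = sum_t alpha_t h_t(x)."""
        return self.ensemble.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels sign(H(x)) in {+1, -1}; H = 0 resolves to +1."""
        return self.ensemble.predict(X)

    def predict_dataframe(self, df: pd.DataFrame) -> pd.DataFrame:
        """Score a feature table using the ensemble's stored feature names."""
        names = self.ensemble.feature_names
        if names is None:
            raise ValueError("ensemble carries no feature names; use predict()")
        X = df[names].to_numpy(dtype=float)
        out = df.copy()
        out["score"] = self.predict_score(X)
        out["prediction"] = self.predict(X)
        return out

    # -- diagnostics --------------------------------------------------------

    @property
    def n_stages(self) -> int:
        return self.ensemble.n_stages

    @property
    def alphas(self) -> np.ndarray:
        return self.ensemble.alphas

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": r.t, "alpha": r.alpha, "n_pseudo": r.n_pseudo,
                    "n_pseudo_pos": r.n_pseudo_pos, "n_pseudo_neg": r.n_pseudo_neg,
                    "appended": r.appended,
                }
                for r in self.ensemble.history
            ]
        )

    def summary(self) -> str:
        e = self.ensemble
        lines = [
            "Semi-supervised boosting SVM results",
            "=" * 44,
            f"{'boosting stages':<28}{e.n_stages:>16}",
            f"{'max rounds (T)':<28}{e.T_max:>16}",
            f"{'similarity scale sigma':<28}{e.sigma:>16.4g}",
            f"{'label/unlabel weight C':<28}{e.C:>16.4g}",
            f"{'margin threshold tau':<28}{e.threshold:>16.4g}",
            f"{'top fraction':<28}{e.top_frac:>16.4g}",
            f"{'training seed':<28}{self.seed:>16}",
            "-" * 44,
            f"{'round':>6}{'alpha':>12}{'pseudo(+)':>12}{'pseudo(-)':>12}",
        ]
        for r in e.history:
            lines.append(
                f"{r.t:>6}{r.alpha:>12.4f}{r.n_pseudo_pos:>12}{r.n_pseudo_neg:>12}"
            )
        return "\n".join(lines)

    def plot_alpha_trajectory(self, ax=None):
        """Stage weights alpha_t per boosting round."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = self.history_frame()
        ax.plot(hist["iteration"], hist["alpha"], marker="o")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("boosting round")
        ax.set_ylabel(r"stage weight $\alpha_t$")
        return ax

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        """Persist the fitted ensemble (joblib; format version recorded)."""
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "ensemble": self.ensemble,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "HotspotSemiBoostResults":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version!r}")
        return cls(model=None, ensemble=payload["ensemble"], seed=payload.get("seed", 0))
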