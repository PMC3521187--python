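"""Run configuration, similarity-scale grid search and published presets."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .evaluation import kfold_cv, semiboost_trainer
from .semiboost import SampleSet

logger = logging.getLogger(__name__)

#: Published best feature subsets, keyed by preset name, mapped onto this
#: package's canonical feature schema.  "unbound" is used where the source
#: leaves the state of a per-state feature unstated.
FEATURE_PRESETS: dict[str, list[str]] = {
    "dataset1-subset": [
        "rc_asa_side_chain",      # relative change in side-chain ASA upon complexation
        "rc_pi_side_chain_mean",  # relative change in side-chain mean PI
        "core_rim",
        "sa_ratio5",
        "rasa_total_unbound",     # total RASA
        "delta_tot",
    ],
    "dataset2-subset": [
        "sa_ratio5",
        "rc_pi_side_chain_mean",
        "rc_pi_min",              # relative change in minimal PI
        "rc_asa_total",           # relative change in total ASA
        "rasa_side_chain_unbound",  # side-chain RASA
        "rc_asa_polar",           # relative change in polar ASA
    ],
}


@dataclass
class RunConfig:
    """All tunables of the pipeline, serializable to a single JSON file."""

    sigma: float = 3.0
    sigma_grid: list[float] = field(default_factory=lambda: [float(s) for s in range(1, 11)])
    C: float | str = "auto"
    T: int = 20
    threshold: float = 0.3
    top_frac: float = 0.10
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    dpx_threshold: float = 0.0
    sa_ratio_form: str = "delta_times_max_over_unb"
    plast_form: str = "ratio_times_max"
    confidence: str = "normalized"
    ddg_threshold: float = 2.0
    k_folds: int = 10
    seed: int = 0
    feature_subset: list[str] | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0 or not self.sigma_grid:
            raise ValueError("sigma must be positive and the grid non-empty")
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac must lie in (0, 1]")
        if self.T < 1 or self.n_sphere_points < 10:
            raise ValueError("T must be >= 1 and n_sphere_points >= 10")
        if isinstance(self.C, str) and self.C != "auto":
            raise ValueError("C must be a number or 'auto'")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def fingerprint(self) -> str:
        """Short stable digest of the configuration, for output manifests."""
        import hashlib

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def sigma_grid_search(
    data: SampleSet,
    grid: list[float] | None = None,
    k: int = 10,
    seed: int = 0,
    trainer_kwargs: dict | None = None,
    evaluator=None,
) -> tuple[float, pd.DataFrame]:
    """Pick the similarity scale by cross-validated F1 over a grid.

    Evaluates k-fold CV per sigma (via ``evaluator(data, sigma)`` if given,
    else the transductive k-fold protocol) and returns the argmax, ties
    resolved toward the smaller sigma, together with the full per-sigma
    table.
    """
    if grid is None:
        grid = [float(s) for s in range(1, 11)]
    if not grid:
        raise ValueError("sigma grid is empty")
    trainer_kwargs = trainer_kwargs or {}
    rows = []
    for sigma in grid:
        if evaluator is not None:
            report = evaluator(data, sigma)
        else:
            report = kfold_cv(data, k=k, trainer=semiboost_trainer(sigma=sigma, **trainer_kwargs), seed=seed)
        rows.append(
            {
                "sigma": sigma, "recall": report.recall, "precision": report.precision,
                "specificity": report.specificity, "accuracy": report.accuracy,
                "f1": report.f1,
            }
        )
    table = pd.DataFrame(rows)
    best_idx = table.sort_values(["f1", "sigma"], ascending=[False, True]).index[0]
    best_sigma = float(table.loc[best_idx, "sigma"])
    logger.info("sigma grid search: best sigma %.3g (F1 %.4f)", best_sigma, table.loc[best_idx, "f1"])
    return best_sigma, table
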