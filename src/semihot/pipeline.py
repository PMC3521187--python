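"""End-to-end workflow: PDB + annotation table -> per-residue predictions.

The pipeline extracts structure and sequence features for every interface
residue of a complex, labels the residues that appear in the user's
annotation table (hot spot when ddG >= 2.0 kcal/mol), treats the remaining
interface residues as the unlabeled pool, trains the semi-supervised
boosting SVM and scores every residue.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import FEATURE_PRESETS, RunConfig
from .features import extract_structure_features, structure_feature_names
from .model import HotspotSemiBoost, HotspotSemiBoostResults
from .pdbio import Structure, read_structure
from .seqfeat import SEQ_FEATURE_NAMES, sequence_features
from .synthetic import label_from_ddg
from .tables import normalize_residue_name

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["chain", "resnum", "icode", "residue", "side", "seq_index", "n_interface"]


def all_feature_names() -> list[str]:
    return structure_feature_names() + list(SEQ_FEATURE_NAMES)


def extract_feature_table(
    structure: Structure,
    side1: list[str],
    side2: list[str],
    config: RunConfig | None = None,
    map_nonstandard: bool = True,
) -> pd.DataFrame:
    """Structure + sequence features, one row per interface residue."""
    cfg = config or RunConfig()
    df = extract_structure_features(
        structure, side1, side2,
        probe_radius=cfg.probe_radius,
        n_sphere_points=cfg.n_sphere_points,
        dpx_threshold=cfg.dpx_threshold,
        sa_ratio_form=cfg.sa_ratio_form,
        plast_form=cfg.plast_form,
    )
    seq_rows = []
    for name in df["residue"]:
        try:
            seq_rows.append(sequence_features(name, map_nonstandard=map_nonstandard))
        except KeyError:
            logger.warning("no sequence features for residue type %s; NA used", name)
            seq_rows.append({k: np.nan for k in SEQ_FEATURE_NAMES})
    seq_df = pd.DataFrame(seq_rows, index=df.index)
    return pd.concat([df, seq_df], axis=1)


@dataclass
class PipelineResult:
    predictions: pd.DataFrame
    results: HotspotSemiBoostResults
    features: pd.DataFrame
    n_labeled: int
    n_unlabeled: int
    skipped_annotations: list[dict]


def _match_annotations(
    features: pd.DataFrame, annotation: pd.DataFrame, ddg_threshold: float
) -> tuple[np.ndarray, list[dict]]:
    """Per-feature-row labels from the annotation table; unmatched rows listed."""
    labels = np.zeros(len(features), dtype=int)
    index = {
        (str(row.chain), int(row.resnum)): i
        for i, row in enumerate(features.itertuples())
    }
    skipped: list[dict] = []
    for _, ann in annotation.iterrows():
        key = (str(ann["chain"]), int(ann["resnum"]))
        i = index.get(key)
        if i is None:
            skipped.append(dict(ann))
            continue
        if "residue" in ann and isinstance(ann["residue"], str) and ann["residue"].strip():
            try:
                expected = normalize_residue_name(ann["residue"], map_nonstandard=True)
                if expected != features.iloc[i]["residue"]:
                    logger.warning(
                        "annotation %s%s names %s but structure has %s; row skipped",
                        key[0], key[1], expected, features.iloc[i]["residue"],
                    )
                    skipped.append(dict(ann))
                    continue
            except KeyError:
                pass
        if "ddg" in ann and pd.notna(ann["ddg"]):
            labels[i] = label_from_ddg(np.array([float(ann["ddg"])]), ddg_threshold)[0]
        elif "label" in ann and pd.notna(ann["label"]):
            labels[i] = int(ann["label"])
        else:
            skipped.append(dict(ann))
    if skipped:
        logger.warning("%d annotation rows did not match any interface residue", len(skipped))
    return labels, skipped


def end_to_end(
    pdb_text: str,
    annotation: pd.DataFrame,
    side1: list[str],
    side2: list[str],
    config: RunConfig | None = None,
) -> PipelineResult:
    """Full workflow on one complex.

    ``annotation`` needs columns chain / resnum plus either ddg (kcal/mol)
    or an explicit label column; residues absent from it become the
    unlabeled pool.  Features used for training follow
    ``config.feature_subset`` (a list or a preset name; default: the
    published 'dataset1-subset').
    """
    cfg = config or RunConfig()
    if annotation is None or len(annotation) == 0:
        raise ValueError("annotation table is empty")
    for col in ("chain", "resnum"):
        if col not in annotation.columns:
            raise ValueError(f"annotation table lacks required column {col!r}")
    structure = read_structure(pdb_text)
    features = extract_feature_table(structure, side1, side2, cfg)
    if len(features) == 0:
        raise ValueError("no interface residues found in the complex")
    labels, skipped = _match_annotations(features, annotation, cfg.ddg_threshold)
    if (labels == 1).sum() == 0 or (labels == -1).sum() == 0:
        raise ValueError("annotations must label at least one hot spot and one non-hot spot")

    subset = cfg.feature_subset or FEATURE_PRESETS["dataset1-subset"]
    if isinstance(subset, str):
        subset = FEATURE_PRESETS[subset]
    missing = [c for c in subset if c not in features.columns]
    if missing:
        raise KeyError(f"feature subset names not in the extracted schema: {missing}")
    X = features[subset].to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=1)
    if not keep.all():
        logger.warning("%d residues dropped for undefined feature values", (~keep).sum())
    model = HotspotSemiBoost(
        X[keep], labels[keep], sigma=cfg.sigma, C=cfg.C, T=cfg.T,
        threshold=cfg.threshold, top_frac=cfg.top_frac,
        confidence=cfg.confidence, feature_names=subset,
    )
    results = model.fit(seed=cfg.seed)
    predictions = features.loc[keep, METADATA_COLUMNS].copy()
    predictions["label"] = labels[keep]
    predictions["score"] = results.predict_score(X[keep])
    predictions["prediction"] = results.predict(X[keep])
    return PipelineResult(
        predictions=predictions,
        results=results,
        features=features,
        n_labeled=int((labels[keep] != 0).sum()),
        n_unlabeled=int((labels[keep] == 0).sum()),
        skipped_annotations=skipped,
    )


def write_manifest(path: Path, config: RunConfig, extra: dict | None = None) -> None:
    """Machine-readable run manifest next to an output file."""
    manifest = {
        "tool": "semihot",
        "version": __version__,
        "config_fingerprint": config.fingerprint(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))
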