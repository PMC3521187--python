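"""Per-residue physicochemical sequence features.

Six properties per amino acid — heavy-atom count, electron-ion interaction
potential, hydrophobicity, hydrophilicity, conformational propensity and
isoelectric point — shipped as a packaged TSV (see the file header for the
exact scales) and exposed as a pure lookup.
"""

from __future__ import annotations

import functools
from pathlib import Path

import pandas as pd

from .tables import _read_packaged_tsv, normalize_residue_name

SEQ_FEATURE_NAMES = (
    "atom_count",
    "eiip",
    "hydrophobicity",
    "hydrophilicity",
    "propensity",
    "isoelectric_point",
)


@functools.lru_cache(maxsize=None)
def _packaged_table() -> pd.DataFrame:
    return load_table(None)


def load_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a sequence-feature table (the packaged one when ``path`` is None)."""
    if path is None:
        df = _read_packaged_tsv("sequence_features.tsv")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SEQ_FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"sequence feature table lacks columns {sorted(missing)}")
    df = df.set_index("residue")
    if len(df) != 20:
        raise ValueError(f"expected 20 standard residues, got {len(df)}")
    bad_pi = df["isoelectric_point"][(df["isoelectric_point"] <= 0) | (df["isoelectric_point"] >= 14)]
    if len(bad_pi):
        raise ValueError(f"isoelectric points outside (0, 14): {list(bad_pi.index)}")
    return df


def sequence_features(
    residue_type: str,
    table: pd.DataFrame | None = None,
    map_nonstandard: bool = False,
) -> dict[str, float]:
    """The 6-vector of sequence properties for one residue type.

    Accepts one- or three-letter codes, case-insensitively.  Non-standard
    residues raise unless ``map_nonstandard`` maps them (e.g. MSE -> MET).
    """
    code = normalize_residue_name(residue_type, map_nonstandard=map_nonstandard)
    df = table if table is not None else _packaged_table()
    row = df.loc[code]
    return {name: float(row[name]) for name in SEQ_FEATURE_NAMES}
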