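"""Packaged lookup tables: van der Waals radii, maxASA, RASA references,
side-chain rotatable-bond counts and hydrophobicity scales.

All tables ship as TSV files under ``semihot/data`` so they can be inspected
and overridden; loading is cached at module level.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Common non-standard residue aliases, applied only on request.
NONSTANDARD_MAP = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HSD": "HIS", "HSE": "HIS"}


def normalize_residue_name(name: str, map_nonstandard: bool = False) -> str:
    """Return the canonical three-letter code, raising on unknown residues."""
    code = name.strip().upper()
    if len(code) == 1 and code in ONE_TO_THREE:
        code = ONE_TO_THREE[code]
    if map_nonstandard and code in NONSTANDARD_MAP:
        code = NONSTANDARD_MAP[code]
    if code not in THREE_TO_ONE:
        raise KeyError(f"unknown residue type {name!r}")
    return code


def _read_packaged_tsv(filename: str) -> pd.DataFrame:
    with resources.files("semihot.data").joinpath(filename).open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@functools.lru_cache(maxsize=None)
def vdw_radii_table() -> dict[str, float]:
    df = _read_packaged_tsv("vdw_radii.tsv")
    return dict(zip(df["element"], df["radius"]))


def vdw_radius(element: str) -> float:
    table = vdw_radii_table()
    return table.get(element.upper(), table["DEFAULT"] if "DEFAULT" in table else table["default"])


@functools.lru_cache(maxsize=None)
def max_asa_table() -> dict[str, float]:
    df = _read_packaged_tsv("max_asa.tsv")
    return dict(zip(df["residue"], df["max_asa"]))


def max_asa(residue_name: str) -> float:
    return max_asa_table()[normalize_residue_name(residue_name)]


@functools.lru_cache(maxsize=None)
def rasa_reference_table() -> dict[str, dict[str, float]]:
    """Per-attribute reference ASA (synthetic, see the data file header)."""
    df = _read_packaged_tsv("rasa_reference_synthetic.tsv")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out[row["residue"]] = {
            attr: float(row[attr])
            for attr in ("total", "backbone", "side_chain", "polar", "non_polar")
        }
    return out


@functools.lru_cache(maxsize=None)
def rotatable_bonds_table() -> dict[str, int]:
    df = _read_packaged_tsv("rotatable_bonds.tsv")
    return {r: int(n) for r, n in zip(df["residue"], df["rotatable_bonds"])}


def rotatable_bonds(residue_name: str) -> int:
    return rotatable_bonds_table()[normalize_residue_name(residue_name)]


@functools.lru_cache(maxsize=None)
def hydrophobicity_table() -> dict[str, float]:
    """Kyte-Doolittle hydropathy, keyed by three-letter code."""
    df = _read_packaged_tsv("sequence_features.tsv")
    return dict(zip(df["residue"], df["hydrophobicity"]))


def reported_performance() -> pd.DataFrame:
    """Published benchmark metric rows used for internal-consistency checks."""
    return _read_packaged_tsv("reported_performance.tsv")
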