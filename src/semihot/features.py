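"""Residue-level structure features for interface residues.

Three families of descriptors are computed for every interface residue:

* per-state PSAIA-style aggregates of ASA / relative ASA (five attributes:
  total, backbone, side-chain, polar, non-polar) and of depth and
  protrusion indices (four attributes: total mean, side-chain mean, max,
  min), in both the bound (complexed) and unbound (chain group extracted
  verbatim) states — 36 features;
* relative changes between the states, RcASA = (ASA_unb - ASA_bnd)/ASA_unb,
  RcDI = (DI_bnd - DI_unb)/DI_bnd, RcPI = (PI_unb - PI_bnd)/PI_unb, applied
  attribute-wise — 13 features;
* neighbourhood / burial descriptors in the KFC2 tradition: DELTA_TOT,
  SA_RATIO5, CORE_RIM, POS_PER, rotatable-bond counts ROT4/ROT5 and their
  distance-weighted forms WT_ROT4/WT_ROT5, neighbour-atom counts
  ATMN4/ATMN5, local plasticity PLAST4/PLAST5, hydrophobic neighbourhood
  HP5, shell atomic densities FP9N/FP9E/FP10N/FP10E and the residue's
  maxASA.

The interface itself is defined operationally: a residue is interfacial
when its total ASA increases by more than ``min_delta`` when its chain
group is taken out of the complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import geometry
from .pdbio import Residue, ResidueKey, Structure
from .tables import (
    hydrophobicity_table,
    max_asa,
    normalize_residue_name,
    rasa_reference_table,
    rotatable_bonds_table,
)

logger = logging.getLogger(__name__)

ASA_ATTRS = ("total", "backbone", "side_chain", "polar", "non_polar")
DI_ATTRS = ("total_mean", "side_chain_mean", "max", "min")

#: Interface membership: ASA gain on unbinding must exceed this, A^2.
INTERFACE_MIN_DELTA = 0.1


@dataclass
class ResidueStructFeatures:
    """Per-state aggregates for one residue."""

    key: ResidueKey
    residue_name: str
    state: str  # "bound" | "unbound"
    asa: dict[str, float]
    rasa: dict[str, float]
    di: dict[str, float]
    pi: dict[str, float]


@dataclass
class InterfaceResidue:
    key: ResidueKey
    residue_name: str
    side: int  # 1 or 2
    seq_index: int  # 1-based rank in the ordered interface list
    n_interface: int
    delta_asa: float


# ---------------------------------------------------------------------------
# aggregation


def aggregate_residue(residue: Residue, per_atom_values: np.ndarray, kind: str) -> dict[str, float]:
    """Aggregate per-atom values over one residue.

    ``kind`` in {"asa", "rasa"} produces sums over the five atom subsets;
    {"di", "pi"} produces total mean / side-chain mean / max / min.  A
    residue without side-chain atoms (glycine) gets 0 for the side-chain
    aggregates.
    """
    values = np.asarray(per_atom_values, dtype=float)
    if len(residue.atoms) == 0:
        raise ValueError(f"residue {residue.key}: no atoms to aggregate")
    if values.shape != (len(residue.atoms),):
        raise ValueError("per_atom_values length does not match the residue")
    side_mask = np.array([not a.is_backbone for a in residue.atoms])
    if kind in ("asa", "rasa"):
        polar = np.array([a.is_polar for a in residue.atoms])
        non_polar = np.array([a.element == "C" for a in residue.atoms])
        return {
            "total": float(values.sum()),
            "backbone": float(values[~side_mask].sum()),
            "side_chain": float(values[side_mask].sum()),
            "polar": float(values[polar].sum()),
            "non_polar": float(values[non_polar].sum()),
        }
    if kind in ("di", "pi"):
        if side_mask.any():
            side_mean = float(values[side_mask].mean())
        else:
            logger.debug("residue %s: no side-chain atoms, side-chain mean set to 0", residue.key)
            side_mean = 0.0
        return {
            "total_mean": float(values.mean()),
            "side_chain_mean": side_mean,
            "max": float(values.max()),
            "min": float(values.min()),
        }
    raise ValueError(f"unknown aggregation kind {kind!r}")


def compute_rasa(residue_asa: dict[str, float], residue_type: str) -> dict[str, float]:
    """Relative ASA: each attribute divided by its extended-tripeptide reference."""
    code = normalize_residue_name(residue_type)
    ref = rasa_reference_table()[code]
    out: dict[str, float] = {}
    for attr in ASA_ATTRS:
        denom = ref[attr]
        if denom == 0.0:
            logger.debug("RASA %s reference is 0 for %s; value set to 0", attr, code)
            out[attr] = 0.0
        else:
            out[attr] = residue_asa[attr] / denom
    return out


# ---------------------------------------------------------------------------
# per-state feature computation


def compute_state_features(
    structure: Structure,
    state: str,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    dpx_threshold: float = 0.0,
    pi_radius: float = geometry.PI_SPHERE_RADIUS,
    mean_atom_volume: float = geometry.MEAN_ATOM_VOLUME,
) -> dict[ResidueKey, ResidueStructFeatures]:
    """ASA/RASA/DI/PI aggregates for every residue of ``structure``."""
    asa = geometry.compute_sasa(structure, probe_radius, n_sphere_points)
    dpx = geometry.compute_depth_index(structure, asa, dpx_threshold)
    pi = geometry.compute_protrusion_index(structure, pi_radius, mean_atom_volume)
    out: dict[ResidueKey, ResidueStructFeatures] = {}
    pos = 0
    for residue in structure.residues():
        n = len(residue.atoms)
        sl = slice(pos, pos + n)
        pos += n
        res_asa = aggregate_residue(residue, asa[sl], "asa")
        try:
            res_rasa = compute_rasa(res_asa, residue.name)
        except KeyError:
            logger.warning("residue %s (%s): no RASA reference, RASA set to 0",
                           residue.key, residue.name)
            res_rasa = {attr: 0.0 for attr in ASA_ATTRS}
        out[residue.key] = ResidueStructFeatures(
            key=residue.key,
            residue_name=residue.name,
            state=state,
            asa=res_asa,
            rasa=res_rasa,
            di=aggregate_residue(residue, dpx[sl], "di"),
            pi=aggregate_residue(residue, pi[sl], "pi"),
        )
    return out


# ---------------------------------------------------------------------------
# relative changes and KFC2-style descriptors


def _relative_change(numer: float, denom: float, label: str) -> float:
    if denom == 0.0:
        logger.debug("relative change %s: zero denominator, value set to 0", label)
        return 0.0
    return numer / denom


def compute_relative_changes(
    bound: ResidueStructFeatures, unbound: ResidueStructFeatures
) -> dict[str, dict[str, float]]:
    """Attribute-wise relative changes between unbound and bound states."""
    if bound.key != unbound.key:
        raise ValueError(f"residue mismatch: {bound.key} vs {unbound.key}")
    rc_asa = {
        attr: _relative_change(
            unbound.asa[attr] - bound.asa[attr], unbound.asa[attr], f"asa.{attr}"
        )
        for attr in ASA_ATTRS
    }
    rc_di = {
        attr: _relative_change(
            bound.di[attr] - unbound.di[attr], bound.di[attr], f"di.{attr}"
        )
        for attr in DI_ATTRS
    }
    rc_pi = {
        attr: _relative_change(
            unbound.pi[attr] - bound.pi[attr], unbound.pi[attr], f"pi.{attr}"
        )
        for attr in DI_ATTRS
    }
    return {"rc_asa": rc_asa, "rc_di": rc_di, "rc_pi": rc_pi}


def compute_kfc2_features(
    bound: ResidueStructFeatures,
    unbound: ResidueStructFeatures,
    residue_type: str,
    seq_index: int,
    n_interface: int,
    sa_ratio_form: str = "delta_times_max_over_unb",
) -> dict[str, float]:
    """DELTA_TOT, SA_RATIO5, CORE_RIM and POS_PER for one interface residue.

    ``sa_ratio_form`` selects between the two possible readings of the
    SA_RATIO5 fraction: ``delta_times_max_over_unb`` (default,
    DELTA_TOT * maxASA / ASA_unb) and ``delta_over_max`` (DELTA_TOT / maxASA).
    """
    asa_unb = unbound.asa["total"]
    asa_bnd = bound.asa["total"]
    if asa_unb == 0.0:
        raise ValueError(f"residue {bound.key}: unbound total ASA is 0")
    if not 1 <= seq_index <= n_interface:
        raise ValueError("seq_index must lie in [1, n_interface]")
    delta_tot = asa_unb - asa_bnd
    core_rim = delta_tot / asa_unb
    m = max_asa(residue_type)
    if sa_ratio_form == "delta_times_max_over_unb":
        sa_ratio5 = delta_tot * m / asa_unb
    elif sa_ratio_form == "delta_over_max":
        sa_ratio5 = delta_tot / m
    else:
        raise ValueError(f"unknown sa_ratio_form {sa_ratio_form!r}")
    return {
        "delta_tot": delta_tot,
        "core_rim": core_rim,
        "sa_ratio5": sa_ratio5,
        "pos_per": core_rim * seq_index / n_interface,
        "max_asa": m,
    }


def compute_neighbor_features(
    structure_bound: Structure,
    residue_key: ResidueKey,
    radii: tuple[float, float] = (4.0, 5.0),
    hp_radius: float = 5.0,
    fp_radii: tuple[float, float] = (9.0, 10.0),
    plast_form: str = "ratio_times_max",
) -> dict[str, float]:
    """Neighbourhood descriptors of one residue in the complexed structure.

    A neighbour is any other residue with at least one atom within the
    radius of any atom of the target.  ROTr sums side-chain rotatable-bond
    counts over neighbours, WT_ROTr weights each neighbour by
    ``1 - d/r`` at its closest-approach distance d, ATMNr counts non-target
    atoms near the target, and PLASTr = (WT_ROTr / ATMNr) * maxASA (or the
    alternative reading WT_ROTr / (ATMNr * maxASA) with
    ``plast_form='ratio_over_max'``).  FPrN counts atoms of other residues
    within ``fp_radii`` of the target centroid and FPrE divides by the
    sphere volume (an atomic-density measure).
    """
    target = structure_bound.get_residue(residue_key)
    target_coords = np.array([a.coords for a in target.atoms])
    others: list[tuple[ResidueKey, str, np.ndarray]] = []
    other_coords: list[np.ndarray] = []
    other_res_idx: list[int] = []
    for res in structure_bound.residues():
        if res.key == residue_key:
            continue
        others.append((res.key, res.name, np.array([a.coords for a in res.atoms])))
        for a in res.atoms:
            other_coords.append(a.coords)
            other_res_idx.append(len(others) - 1)
    rot_table = rotatable_bonds_table()
    hp_table = hydrophobicity_table()
    out: dict[str, float] = {}

    if not others:
        for r in radii:
            tag = f"{int(r)}" if float(r).is_integer() else f"{r:g}"
            out.update({f"rot{tag}": 0.0, f"atmn{tag}": 0.0,
                        f"wt_rot{tag}": 0.0, f"plast{tag}": 0.0})
        out["hp5"] = 0.0
        for fr in fp_radii:
            tag = f"{int(fr)}" if float(fr).is_integer() else f"{fr:g}"
            out[f"fp{tag}n"] = 0.0
            out[f"fp{tag}e"] = 0.0
        return out

    other_coords_arr = np.array(other_coords)
    other_res_idx_arr = np.array(other_res_idx)
    # closest approach of each other residue to the target
    tree = cKDTree(target_coords)
    d_atom, _ = tree.query(other_coords_arr, k=1)
    n_other = len(others)
    d_res = np.full(n_other, np.inf)
    np.minimum.at(d_res, other_res_idx_arr, d_atom)

    m = max_asa(target.name) if target.name in rot_table else None

    def _lookup(table: dict[str, float], name: str, default: float = 0.0) -> float:
        try:
            return table[normalize_residue_name(name)]
        except KeyError:
            logger.debug("no table entry for residue type %s; 0 used", name)
            return default

    for r in radii:
        tag = f"{int(r)}" if float(r).is_integer() else f"{r:g}"
        neigh = d_res <= r
        rot = sum(_lookup(rot_table, others[i][1]) for i in np.flatnonzero(neigh))
        wt_rot = sum(
            _lookup(rot_table, others[i][1]) * (1.0 - d_res[i] / r)
            for i in np.flatnonzero(neigh)
        )
        atmn = int((d_atom <= r).sum())
        if atmn == 0:
            logger.debug("residue %s: no atoms within %.1f A, PLAST set to 0", residue_key, r)
            plast = 0.0
        elif m is None:
            plast = 0.0
        elif plast_form == "ratio_times_max":
            plast = wt_rot / atmn * m
        elif plast_form == "ratio_over_max":
            plast = wt_rot / (atmn * m)
        else:
            raise ValueError(f"unknown plast_form {plast_form!r}")
        out[f"rot{tag}"] = float(rot)
        out[f"atmn{tag}"] = float(atmn)
        out[f"wt_rot{tag}"] = float(wt_rot)
        out[f"plast{tag}"] = float(plast)

    hp_neigh = d_res <= hp_radius
    out["hp5"] = float(sum(_lookup(hp_table, others[i][1]) for i in np.flatnonzero(hp_neigh)))

    centroid = target.centroid()
    d_centroid = np.linalg.norm(other_coords_arr - centroid, axis=1)
    for fr in fp_radii:
        tag = f"{int(fr)}" if float(fr).is_integer() else f"{fr:g}"
        count = int((d_centroid <= fr).sum())
        volume = 4.0 / 3.0 * np.pi * fr**3
        out[f"fp{tag}n"] = float(count)
        out[f"fp{tag}e"] = count / volume
    return out


# ---------------------------------------------------------------------------
# interface identification


def _per_residue_total_asa(
    structure: Structure, probe_radius: float, n_sphere_points: int
) -> dict[ResidueKey, float]:
    asa = geometry.compute_sasa(structure, probe_radius, n_sphere_points)
    totals: dict[ResidueKey, float] = {}
    pos = 0
    for res in structure.residues():
        n = len(res.atoms)
        totals[res.key] = float(asa[pos : pos + n].sum())
        pos += n
    return totals


def identify_interface_residues(
    complex_structure: Structure,
    side1: list[str],
    side2: list[str],
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    min_delta: float = INTERFACE_MIN_DELTA,
) -> list[InterfaceResidue]:
    """Residues whose total ASA grows by more than ``min_delta`` on unbinding.

    The partition must cover disjoint, known chains.  The returned list is
    ordered by chain then residue number; ``seq_index`` is the 1-based rank
    and ``n_interface`` the list length.
    """
    s1, s2 = set(side1), set(side2)
    if s1 & s2:
        raise ValueError(f"chains {sorted(s1 & s2)} appear on both sides")
    known = set(complex_structure.chain_ids())
    unknown = (s1 | s2) - known
    if unknown:
        raise KeyError(f"partition references unknown chain(s) {sorted(unknown)}")
    if not s1 or not s2:
        raise ValueError("both sides of the partition must name at least one chain")

    bound = _per_residue_total_asa(complex_structure, probe_radius, n_sphere_points)
    records: list[tuple[ResidueKey, str, int, float]] = []
    for side_num, side in ((1, s1), (2, s2)):
        sub = complex_structure.subset(side)
        unbound = _per_residue_total_asa(sub, probe_radius, n_sphere_points)
        for res in sub.residues():
            delta = unbound[res.key] - bound[res.key]
            if delta > min_delta:
                records.append((res.key, res.name, side_num, delta))
    records.sort(key=lambda r: (r[0][0], r[0][1], r[0][2]))
    n = len(records)
    return [
        InterfaceResidue(
            key=key, residue_name=name, side=side, seq_index=i + 1,
            n_interface=n, delta_asa=delta,
        )
        for i, (key, name, side, delta) in enumerate(records)
    ]


# ---------------------------------------------------------------------------
# full feature table


def structure_feature_names() -> list[str]:
    names: list[str] = []
    for state in ("bound", "unbound"):
        names += [f"asa_{a}_{state}" for a in ASA_ATTRS]
        names += [f"rasa_{a}_{state}" for a in ASA_ATTRS]
        names += [f"di_{a}_{state}" for a in DI_ATTRS]
        names += [f"pi_{a}_{state}" for a in DI_ATTRS]
    names += [f"rc_asa_{a}" for a in ASA_ATTRS]
    names += [f"rc_di_{a}" for a in DI_ATTRS]
    names += [f"rc_pi_{a}" for a in DI_ATTRS]
    names += [
        "delta_tot", "core_rim", "sa_ratio5", "pos_per", "max_asa",
        "rot4", "rot5", "hp5", "atmn4", "atmn5", "wt_rot4", "wt_rot5",
        "plast4", "plast5", "fp9n", "fp9e", "fp10n", "fp10e",
    ]
    return names


def extract_structure_features(
    complex_structure: Structure,
    side1: list[str],
    side2: list[str],
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    dpx_threshold: float = 0.0,
    sa_ratio_form: str = "delta_times_max_over_unb",
    plast_form: str = "ratio_times_max",
) -> pd.DataFrame:
    """One row of structure features per interface residue.

    Bound-state descriptors are computed on the full complex; unbound-state
    descriptors on each chain group extracted verbatim.  The first columns
    identify the residue (chain, resnum, icode, residue, side, seq_index,
    n_interface); the rest follow :func:`structure_feature_names`.
    """
    interface = identify_interface_residues(
        complex_structure, side1, side2, probe_radius, n_sphere_points
    )
    if not interface:
        logger.warning("no interface residues found")
        return pd.DataFrame(
            columns=["chain", "resnum", "icode", "residue", "side",
                     "seq_index", "n_interface", *structure_feature_names()]
        )
    bound_feats = compute_state_features(
        complex_structure, "bound", probe_radius, n_sphere_points, dpx_threshold
    )
    unbound_feats: dict[ResidueKey, ResidueStructFeatures] = {}
    for side in (side1, side2):
        sub = complex_structure.subset(side)
        unbound_feats.update(
            compute_state_features(sub, "unbound", probe_radius, n_sphere_points, dpx_threshold)
        )

    rows: list[dict] = []
    for ir in interface:
        b, u = bound_feats[ir.key], unbound_feats[ir.key]
        row: dict[str, float | str | int] = {
            "chain": ir.key[0], "resnum": ir.key[1], "icode": ir.key[2],
            "residue": ir.residue_name, "side": ir.side,
            "seq_index": ir.seq_index, "n_interface": ir.n_interface,
        }
        for state, feats in (("bound", b), ("unbound", u)):
            for a in ASA_ATTRS:
                row[f"asa_{a}_{state}"] = feats.asa[a]
                row[f"rasa_{a}_{state}"] = feats.rasa[a]
            for a in DI_ATTRS:
                row[f"di_{a}_{state}"] = feats.di[a]
                row[f"pi_{a}_{state}"] = feats.pi[a]
        rc = compute_relative_changes(b, u)
        for a in ASA_ATTRS:
            row[f"rc_asa_{a}"] = rc["rc_asa"][a]
        for a in DI_ATTRS:
            row[f"rc_di_{a}"] = rc["rc_di"][a]
            row[f"rc_pi_{a}"] = rc["rc_pi"][a]
        try:
            row.update(
                compute_kfc2_features(
                    b, u, ir.residue_name, ir.seq_index, ir.n_interface, sa_ratio_form
                )
            )
        except KeyError:
            logger.warning("residue %s (%s): no maxASA entry, burial features set to NA",
                           ir.key, ir.residue_name)
            row.update({k: np.nan for k in ("delta_tot", "core_rim", "sa_ratio5",
                                            "pos_per", "max_asa")})
        row.update(
            compute_neighbor_features(complex_structure, ir.key, plast_form=plast_form)
        )
        rows.append(row)
    return pd.DataFrame(rows)
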