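"""Atom-level geometric descriptors: solvent accessibility, depth, protrusion.

Solvent-accessible surface area (SASA) uses the Shrake-Rupley rolling-probe
construction via biotite's implementation with this package's radius table
(deterministic Fibonacci point distribution).  Depth index (DPX) is the
distance from a buried atom to the nearest solvent-accessible atom, and the
protrusion index (PI) compares occupied and empty volume inside a fixed
sphere around each atom.
"""

from __future__ import annotations

import logging

import numpy as np
import biotite.structure as struc
from scipy.spatial import cKDTree

from .pdbio import Structure

logger = logging.getLogger(__name__)

#: Mean atomic volume found in proteins, A^3 (CX/PSAIA convention).
MEAN_ATOM_VOLUME = 20.1

#: Sphere radius for the protrusion index, A.
PI_SPHERE_RADIUS = 10.0


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in A^2.

    Shrake-Rupley with ``n_sphere_points`` test points per atom; the point
    set is deterministic, so results are bit-reproducible for a fixed input.
    """
    if n_sphere_points < 10:
        raise ValueError("n_sphere_points must be >= 10")
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    coords = structure.coords()
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["UNK"] * n)
    arr.atom_name = np.array(["X"] * n)
    arr.element = np.array([a.element for a in structure.atoms])
    asa = struc.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=n_sphere_points,
        vdw_radii=structure.radii(),
    )
    return np.asarray(asa, dtype=float)


def compute_depth_index(
    structure: Structure,
    atom_asa: np.ndarray,
    accessibility_threshold: float = 0.0,
) -> np.ndarray:
    """Per-atom depth (DPX) in A.

    Atoms with ASA above ``accessibility_threshold`` are solvent accessible
    and have depth 0; every other atom gets its minimum Euclidean distance
    to an accessible atom.
    """
    atom_asa = np.asarray(atom_asa, dtype=float)
    if atom_asa.shape != (structure.n_atoms,):
        raise ValueError("atom_asa length does not match the structure")
    accessible = atom_asa > accessibility_threshold
    if not accessible.any():
        raise ValueError(
            "no solvent-accessible atom in structure "
            f"(threshold {accessibility_threshold} A^2)"
        )
    coords = structure.coords()
    dpx = np.zeros(structure.n_atoms)
    buried = ~accessible
    if buried.any():
        tree = cKDTree(coords[accessible])
        dpx[buried], _ = tree.query(coords[buried], k=1)
    return dpx


def compute_protrusion_index(
    structure: Structure,
    sphere_radius: float = PI_SPHERE_RADIUS,
    mean_atom_volume: float = MEAN_ATOM_VOLUME,
) -> np.ndarray:
    """Per-atom protrusion index PI = V_ext / V_int.

    V_int is the number of atoms (the atom itself included) within
    ``sphere_radius`` of each atom times ``mean_atom_volume``; V_ext is the
    rest of the sphere volume.  A sphere fuller than its own volume clamps
    to PI = 0.
    """
    radii = structure.radii()
    if sphere_radius <= radii.max():
        raise ValueError("sphere_radius must exceed the largest vdW radius")
    coords = structure.coords()
    tree = cKDTree(coords)
    counts = np.array([len(tree.query_ball_point(c, sphere_radius)) for c in coords])
    sphere_volume = 4.0 / 3.0 * np.pi * sphere_radius**3
    v_int = counts * mean_atom_volume
    pi = np.empty(len(coords))
    overfull = v_int >= sphere_volume
    if overfull.any():
        logger.info("protrusion index clamped to 0 for %d overfull atoms", overfull.sum())
    pi[overfull] = 0.0
    pi[~overfull] = (sphere_volume - v_int[~overfull]) / v_int[~overfull]
    return pi
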