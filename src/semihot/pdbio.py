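"""Protein structure container and PDB reading.

The in-memory model is deliberately small: chains hold residues, residues
hold heavy atoms with coordinates, a van der Waals radius class and the
backbone / polar flags that the surface-area bookkeeping needs.  Parsing is
delegated to gemmi; this module only filters (waters, HETATM, hydrogens,
alternate locations) and maps into the domain types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .tables import vdw_radius

logger = logging.getLogger(__name__)

#: Backbone heavy-atom names; everything else is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Residue names treated as water and dropped on input.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

ResidueKey = tuple[str, int, str]


class PDBParseError(ValueError):
    """Raised when a PDB text cannot be interpreted."""


@dataclass
class Atom:
    """One heavy atom.

    ``is_polar`` follows the surface-area convention used throughout:
    nitrogen and oxygen atoms are polar, carbon atoms are non-polar and
    anything else (sulfur, phosphorus) belongs to neither class.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    vdw_radius: float
    is_backbone: bool
    is_polar: bool
    residue_key: ResidueKey
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdW radius must be positive")


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def chain_id(self) -> str:
        return self.key[0]

    @property
    def number(self) -> int:
        return self.key[1]

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_backbone]

    def centroid(self) -> np.ndarray:
        return np.mean([a.coords for a in self.atoms], axis=0)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    """Chains -> residues -> atoms, in file order."""

    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index_atoms()

    def _index_atoms(self) -> None:
        self._atoms: list[Atom] = [
            a for ch in self.chains for r in ch.residues for a in r.atoms
        ]

    @property
    def atoms(self) -> list[Atom]:
        return self._atoms

    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    def residues(self) -> list[Residue]:
        return [r for ch in self.chains for r in ch.residues]

    def chain_ids(self) -> list[str]:
        return [ch.chain_id for ch in self.chains]

    def get_chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in structure")

    def get_residue(self, key: ResidueKey) -> Residue:
        for ch in self.chains:
            if ch.chain_id != key[0]:
                continue
            for r in ch.residues:
                if r.key == key:
                    return r
        raise KeyError(f"no residue {key!r} in structure")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self._atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self._atoms], dtype=float)

    def atom_index(self) -> dict[int, int]:
        """Map ``id(atom)`` -> position in the flat atom list."""
        return {id(a): i for i, a in enumerate(self._atoms)}

    def subset(self, chain_ids: set[str] | list[str]) -> "Structure":
        """Extract the named chains verbatim (the 'unbound' state of a side)."""
        wanted = set(chain_ids)
        unknown = wanted - set(self.chain_ids())
        if unknown:
            raise KeyError(f"unknown chain(s) {sorted(unknown)}")
        return Structure(chains=[ch for ch in self.chains if ch.chain_id in wanted])


def _validate_atom_lines(pdb_text: str) -> int:
    """Cheap structural sanity pass so malformed records fail with a line number."""
    n_atom = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if line.startswith("ATOM  "):
            n_atom += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record shorter than 54 columns")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: unparsable coordinates") from exc
    return n_atom


def _infer_element(g_atom: gemmi.Atom) -> str:
    el = g_atom.element.name.upper()
    if el and el != "X":
        return el
    stripped = g_atom.name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def read_structure(pdb_text: str, keep_hetatm: bool = False) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Waters and (by default) HETATM groups are dropped, hydrogens are
    removed, and alternate locations are resolved by keeping the highest
    occupancy conformer of each atom name.  Raises
    :class:`PDBParseError` on malformed ATOM records (with the offending
    line number) and on structures with no usable atoms.
    """
    n_atom_records = _validate_atom_lines(pdb_text)
    if n_atom_records == 0:
        raise PDBParseError("no ATOM records in input")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"gemmi failed to parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no model in PDB text")
    model = st[0]

    chains: list[Chain] = []
    for g_chain in model:
        chain = Chain(chain_id=g_chain.name.strip() or "A")
        for g_res in g_chain:
            if g_res.name in WATER_NAMES:
                continue
            if g_res.het_flag == "H" and not keep_hetatm:
                continue
            icode = g_res.seqid.icode.strip()
            key: ResidueKey = (chain.chain_id, g_res.seqid.num, icode)
            # altloc resolution: per atom name keep the highest occupancy
            best: dict[str, gemmi.Atom] = {}
            for g_atom in g_res:
                if g_atom.is_hydrogen():
                    continue
                prev = best.get(g_atom.name)
                if prev is None or g_atom.occ > prev.occ:
                    best[g_atom.name] = g_atom
            residue = Residue(key=key, name=g_res.name)
            for g_atom in best.values():
                element = _infer_element(g_atom)
                residue.atoms.append(
                    Atom(
                        serial=g_atom.serial,
                        name=g_atom.name,
                        element=element,
                        coords=np.array([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]),
                        vdw_radius=vdw_radius(element),
                        is_backbone=g_atom.name in BACKBONE_ATOMS,
                        is_polar=element in ("N", "O"),
                        residue_key=key,
                        occupancy=g_atom.occ,
                    )
                )
            if residue.atoms:
                residue.atoms.sort(key=lambda a: a.serial)
                chain.residues.append(residue)
        if chain.residues:
            chains.append(chain)
    structure = Structure(chains=chains)
    if structure.n_atoms == 0:
        raise PDBParseError("structure contains no usable heavy atoms")
    logger.debug(
        "parsed structure: %d chains, %d residues, %d atoms",
        len(structure.chains), len(structure.residues()), structure.n_atoms,
    )
    return structure
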