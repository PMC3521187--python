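"""Synthetic fixtures: Gaussian-cluster sample sets and toy PDB complexes.

The cluster generator emulates a labeled-plus-unlabeled feature table with
two isotropic Gaussian classes — the minimal structure under which the
cluster assumption of graph-based pseudo-labeling is exercised.  The toy
complex generator writes a small two-chain poly-alanine PDB with a
controllable number of contacting and remote residue pairs, so the
geometric feature extraction can be verified without downloading real
structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .semiboost import SampleSet


@dataclass
class ClusterSpec:
    """Two-class Gaussian mixture specification.

    ``separation`` is the distance between class means in units of the
    (unit) within-class standard deviation; ``label_noise`` flips each
    labeled point's class with the given probability.
    """

    n_labeled_per_class: int = 10
    n_unlabeled: int = 200
    dim: int = 10
    separation: float = 2.5
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_labeled_per_class, self.n_unlabeled, self.dim) < 0:
            raise ValueError("counts and dimension must be non-negative")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")


def generate_clusters(spec: ClusterSpec) -> tuple[SampleSet, np.ndarray]:
    """Draw a labeled + unlabeled sample set from the mixture.

    Returns the :class:`SampleSet` (unlabeled rows carry label 0) and the
    hidden true labels of the unlabeled rows.  Bit-reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    offset = np.zeros(spec.dim)
    offset[0] = spec.separation / 2.0
    n_l = spec.n_labeled_per_class

    X_pos = rng.standard_normal((n_l, spec.dim)) + offset
    X_neg = rng.standard_normal((n_l, spec.dim)) - offset
    y_lab = np.concatenate([np.ones(n_l, dtype=int), -np.ones(n_l, dtype=int)])
    if spec.label_noise > 0 and n_l > 0:
        flips = rng.random(2 * n_l) < spec.label_noise
        y_lab[flips] *= -1

    true_u = np.where(rng.random(spec.n_unlabeled) < 0.5, 1, -1)
    X_u = rng.standard_normal((spec.n_unlabeled, spec.dim)) + np.outer(true_u, offset)

    X = np.vstack([X_pos, X_neg, X_u])
    y = np.concatenate([y_lab, np.zeros(spec.n_unlabeled, dtype=int)])
    return SampleSet(X=X, y=y), true_u


# ---------------------------------------------------------------------------
# toy structures

# local heavy-atom template of one pseudo-alanine residue: name, element,
# offset from CA.  The CB points along +y so facing chains make side-chain
# contact first.
_RESIDUE_TEMPLATE = [
    ("N", "N", (-1.20, -0.45, 0.00)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("C", "C", (1.25, -0.45, 0.55)),
    ("O", "O", (1.35, -1.60, 0.80)),
    ("CB", "C", (0.10, 1.30, 0.80)),
]

_CA_SPACING = 3.8  # along-chain CA-CA distance, A


def generate_toy_complex(
    n_contact: int,
    n_remote: int = 0,
    seed: int = 0,
    contact_gap: float = 6.0,
    remote_offset: float = 25.0,
) -> str:
    """PDB text of a synthetic two-chain poly-alanine complex.

    Chains A and B run antiparallel to the x axis.  The first ``n_contact``
    residue pairs face each other across ``contact_gap`` angstroms
    (CA-plane to CA-plane, side chains pointing inwards, so cross-chain
    atom contacts fall within ~5 A); the following ``n_remote`` residues of
    each chain are displaced ``remote_offset`` further away from the
    partner chain.  Coordinates get a small seeded jitter.
    """
    if n_contact < 1:
        raise ValueError("n_contact must be >= 1")
    if n_remote < 0:
        raise ValueError("n_remote must be >= 0")
    rng = np.random.default_rng(seed)
    st = gemmi.Structure()
    st.name = "toy-complex"
    model = gemmi.Model("1")
    serial = 1
    for chain_id, y_base, flip in (("A", 0.0, 1.0), ("B", contact_gap, -1.0)):
        chain = gemmi.Chain(chain_id)
        n_res = n_contact + n_remote
        for i in range(n_res):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            res.het_flag = "A"
            # remote residues move away from the partner chain
            y_shift = 0.0 if i < n_contact else flip * remote_offset * -1.0
            for name, element, (dx, dy, dz) in _RESIDUE_TEMPLATE:
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(element)
                jitter = rng.uniform(-0.15, 0.15, size=3)
                x = i * _CA_SPACING + dx + jitter[0]
                y = y_base + flip * dy + y_shift + jitter[1]
                z = dz * flip + jitter[2]
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = 1.0
                atom.b_iso = 0.0
                atom.serial = serial
                serial += 1
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def label_from_ddg(ddg: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """Hot-spot labels from alanine-scanning ddG values (kcal/mol).

    +1 when ddG >= threshold (the 2.0 kcal/mol boundary counts as a hot
    spot), -1 below, and 0 (unlabeled) for missing values.
    """
    ddg = np.asarray(ddg, dtype=float)
    if np.isinf(ddg).any():
        raise ValueError("ddG values must be finite or NaN")
    labels = np.where(ddg >= threshold, 1, -1)
    labels = np.where(np.isnan(ddg), 0, labels)
    return labels.astype(int)
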