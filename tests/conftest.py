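import numpy as np
import pytest

from semihot.pdbio import read_structure
from semihot.synthetic import ClusterSpec, generate_clusters, generate_toy_complex

#: one isolated carbon atom
SINGLE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
    "END\n"
)

#: hand-written 3-residue peptide on chain A plus one residue on chain B
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.989   2.839   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.030   1.580   0.000  1.00  0.00           O
ATOM     10  N   SER A   3       6.224   3.810   0.000  1.00  0.00           N
ATOM     11  CA  SER A   3       7.680   3.789   0.000  1.00  0.00           C
ATOM     12  C   SER A   3       8.232   5.203   0.000  1.00  0.00           C
ATOM     13  O   SER A   3       7.471   6.171   0.000  1.00  0.00           O
ATOM     14  OG  SER A   3       8.212   3.081   1.120  1.00  0.00           O
ATOM     15  CB  SER A   3       8.202   3.062  -1.240  1.00  0.00           C
ATOM     16  N   ALA B   5      30.000  30.000  30.000  1.00  0.00           N
ATOM     17  CA  ALA B   5      31.458  30.000  30.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def three_residue_structure():
    return read_structure(THREE_RESIDUE_PDB)


@pytest.fixture(scope="session")
def toy_complex_pdb():
    return generate_toy_complex(n_contact=4, n_remote=3, seed=7)


@pytest.fixture(scope="session")
def toy_complex(toy_complex_pdb):
    return read_structure(toy_complex_pdb)


@pytest.fixture()
def cluster_data():
    spec = ClusterSpec(n_labeled_per_class=10, n_unlabeled=100, dim=3,
                       separation=6.0, seed=11)
    return generate_clusters(spec)


def random_confidences(rng: np.random.Generator, n: int):
    """Strictly positive random (p, q) pairs for oracle tests."""
    from semihot.semiboost import Confidences

    return Confidences(p=rng.uniform(0.01, 1.0, n), q=rng.uniform(0.01, 1.0, n), C=0.5)
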