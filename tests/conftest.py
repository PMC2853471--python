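import numpy as np
import pytest

from nadbinder import SimConfig, simulate_chains, simulate_pssms


@pytest.fixture(scope="session")
def small_world():
    """20 motif-planted chains with labels and pseudo-profiles."""
    cfg = SimConfig(n_chains=20, seed=7)
    chains, labels, manifest = simulate_chains(cfg)
    profiles = simulate_pssms(chains, labels, cfg)
    return cfg, chains, labels, profiles, manifest


@pytest.fixture(scope="session")
def cv_world():
    """The 150-chain world used for the cross-validated recovery checks."""
    cfg = SimConfig(n_chains=150, seed=11)
    chains, labels, _ = simulate_chains(cfg)
    return cfg, chains, labels


# A hand-written 3-residue protein with one NAD heteroatom 3.0 A from the
# tyrosine OH; distances are exact by construction.
TOY_PDB = """\
HEADER    TOY
ATOM      1  N   GLY A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.500   1.000   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.800   1.000   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      7  CB  ALA A   2       3.800  -1.500   0.000  1.00  0.00           C
ATOM      8  C   ALA A   2       4.800   0.000   0.000  1.00  0.00           C
ATOM      9  O   ALA A   2       5.300   1.000   0.000  1.00  0.00           O
ATOM     10  N   TYR A   3       7.600   1.000   0.000  1.00  0.00           N
ATOM     11  CA  TYR A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM     12  OH  TYR A   3       7.600   5.000   0.000  1.00  0.00           O
ATOM     13  C   TYR A   3       8.600   0.000   0.000  1.00  0.00           C
ATOM     14  O   TYR A   3       9.100   1.000   0.000  1.00  0.00           O
HETATM   15  C1  NAD A 901       7.600   8.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb_text():
    return TOY_PDB


@pytest.fixture
def rng():
    return np.random.default_rng(0)
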