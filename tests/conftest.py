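import numpy as np
import pytest

from hsesite import HelixParams, ProteinChain, ResidueGeometry, make_helix_chain

# Four-residue toy structure: ALA (CA+CB), GLY (CA only), LYS with an A/B
# altloc on CA (B has the higher occupancy, A is listed first), UNK
# (nonstandard), plus a SER lacking its CA and a water HETATM, both of which
# the reader must drop.
TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       0.000   0.000   1.500  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA ALYS A   3       7.600   0.000   0.000  0.40  0.00           C
ATOM      5  CA BLYS A   3       7.700   0.000   0.000  0.60  0.00           C
ATOM      6  CB  LYS A   3       7.600   1.500   0.000  1.00  0.00           C
ATOM      7  CA  UNK A   5      15.200   0.000   0.000  1.00  0.00           C
ATOM      8  CB  SER A   6      19.000   0.000   0.000  1.00  0.00           C
HETATM    9  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def helix30():
    return make_helix_chain(HelixParams(n_residues=30))


def chain_from_points(ca_points, cb_points=None, sequence=None):
    """Build a ProteinChain from raw coordinates for hand-geometry tests."""
    ca_points = [np.asarray(p, dtype=float) for p in ca_points]
    if cb_points is None:
        cb_points = [None] * len(ca_points)
    geometry = [
        ResidueGeometry(ca=ca, cb=None if cb is None else np.asarray(cb, dtype=float))
        for ca, cb in zip(ca_points, cb_points)
    ]
    return ProteinChain(
        id="hand",
        sequence=sequence or "K" * len(ca_points),
        geometry=geometry,
    )
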