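import numpy as np
import pytest

from shbond.structure_io import Atom, LigandInstance, Residue, Structure
from shbond.synthetic import Plant, PlantSpec, SignalSpec, make_feature_table, make_toy_complex
from shbond.model import BoostConfig, train_ensemble


def make_atom(name, element, pos, serial=1, hetero=False):
    return Atom(serial=serial, name=name, element=element,
                coords=np.asarray(pos, dtype=float), is_hetero=hetero)


MINIMAL_PDB = """\
REMARK   2 RESOLUTION.    1.05 ANGSTROMS.
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.250   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.330   1.540   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.970   2.850   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2       5.490   2.700   0.000  1.00  0.00           C
ATOM      8  O   ALA A   2       6.030   1.590   0.000  1.00  0.00           O
ATOM      9  CB  ALA A   2       3.550   3.640   1.250  1.00  0.00           C
ATOM     10  N   SER A   3       6.200   3.830   0.000  1.00  0.00           N
ATOM     11  CA  SER A   3       7.660   3.830   0.000  1.00  0.00           C
ATOM     12  CB  SER A   3       8.210   5.260   0.000  1.00  0.00           C
ATOM     13  OG  SER A   3       9.620   5.260   0.000  1.00  0.00           O
ATOM     14  C   SER A   3       8.200   4.560   1.250  1.00  0.00           C
ATOM     15  O   SER A   3       7.450   5.520   1.600  1.00  0.00           O
TER
HETATM   16  C1  MLA B 101      20.000   0.000   0.000  1.00  0.00           C
HETATM   17  O1  MLA B 101      20.600   1.100   0.000  1.00  0.00           O
HETATM   18  O2  MLA B 101      20.660  -1.190   0.000  1.00  0.00           O
HETATM   19  C2  MLA B 101      18.470   0.000   0.000  1.00  0.00           C
HETATM   20  O   HOH B 201      30.000   0.000   0.000  1.00  0.00           O
HETATM   21  O   HOH B 202      33.000   0.000   0.000  1.00  0.00           O
END
"""

WATERS_ONLY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.250   2.390   0.000  1.00  0.00           O
TER
HETATM    5  O   HOH B 101      10.000   0.000   0.000  1.00  0.00           O
HETATM    6  O   HOH B 102      13.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb_text():
    return MINIMAL_PDB


@pytest.fixture
def waters_only_pdb_text():
    return WATERS_ONLY_PDB


@pytest.fixture
def five_plant_spec():
    """Five planted Ser-hydroxyl bonds at R = 2.4, 2.5, 2.6, 3.0, 3.4 A."""
    return PlantSpec(
        plants=tuple(
            Plant("SER", "alkyl_hydroxyl", r, 170.0)
            for r in (2.4, 2.5, 2.6, 3.0, 3.4)
        ),
        n_decoys=3,
        seed=11,
    )


@pytest.fixture
def five_plant_complex(five_plant_spec):
    return make_toy_complex(five_plant_spec)


@pytest.fixture(scope="session")
def small_table():
    """Small strong-signal feature table shared across model tests."""
    return make_feature_table(SignalSpec(n_shb=150, n_nhb=320, seed=5))


@pytest.fixture(scope="session")
def tiny_ensemble(small_table):
    """A cheap but structurally complete 10-member ensemble."""
    data, _ = small_table
    config = BoostConfig(n_trees=60, depth_grid=(2,), base_seed=1)
    return train_ensemble(data, config), data
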