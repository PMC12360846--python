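import numpy as np
import pytest

from mapgan.volume_io import Atom, AtomicModel, DensityMap

PDB_3ATOMS = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  N   ALA A   1       4.000   5.000   6.000  1.00  0.00           N
ATOM      3  H   ALA A   1       2.000   2.000   2.000  1.00  0.00           H
END
"""


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def pdb_file(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(PDB_3ATOMS)
    return path


def make_model(positions, elements=None, occupancies=None):
    """Build an AtomicModel directly from coordinate rows."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    elements = elements or ["C"] * n
    occupancies = occupancies or [1.0] * n
    z_of = {"C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "FE": 26}
    atoms = [
        Atom(
            element=e,
            atomic_number=z_of[e.upper()],
            position=np.asarray(p, dtype=float),
            occupancy=o,
        )
        for e, p, o in zip(elements, positions, occupancies)
    ]
    return AtomicModel(atoms)


def make_map(data, voxel=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return DensityMap(np.asarray(data, dtype=np.float32), voxel, origin)


@pytest.fixture
def random_map(rng):
    return make_map(rng.random((12, 10, 14)), voxel=(1.5, 1.0, 2.0), origin=(3.0, -2.0, 5.0))
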