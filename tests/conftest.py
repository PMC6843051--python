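import numpy as np
import pytest

from mcgpath import forcefield, toybuilder


QUAD_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA A   4      11.400   0.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA AALA A   2       3.800   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   2       3.900   0.100   0.000  0.40  0.00           C
ATOM      4  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      5  CA  ALA A   4      11.400   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def helix30():
    return toybuilder.make_helix(30)


@pytest.fixture(scope="session")
def helix30_topology(helix30):
    return forcefield.build_topology(helix30)


@pytest.fixture(scope="session")
def hinge_pair():
    return toybuilder.make_hinge_pair(40, 30.0, 120.0)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
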