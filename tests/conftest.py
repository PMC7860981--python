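import numpy as np
import pytest

from ureasurf.sasa import SasaParams

# A hand-written minimal PDB: one ALA with an alt-loc CB pair, one NAG
# ligand, one water.  Fixed-column format, coordinates in Angstrom.
TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  CB AALA A   1       1.980  -0.760   1.220  0.60 10.00           C
ATOM      6  CB BALA A   1       1.950  -0.790   1.190  0.40 10.00           C
HETATM    7  C1  NAG A 201      10.000  10.000  10.000  1.00 10.00           C
HETATM    8  O   HOH A 301      20.000  20.000  20.000  1.00 10.00           O
END
"""


@pytest.fixture
def tiny_pdb_text():
    return TINY_PDB


@pytest.fixture(scope="session")
def fast_params():
    """Reduced mesh density for tests where absolute accuracy is not at stake."""
    return SasaParams(n_points=960)


@pytest.fixture(scope="session")
def study_params():
    """The study's mesh density and surface threshold with a 1.4 A water probe."""
    return SasaParams(probe_radius=1.4, n_points=9600, threshold_pct=25.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
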