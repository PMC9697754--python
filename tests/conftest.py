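import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00 10.00           C
ATOM      3  CA  GLY A   2       2.000   1.000   0.000  1.00 20.00           C
ATOM      4  CA  SER A   3       3.000   1.000   2.000  1.00 30.00           C
END
"""

# residue 2 has altlocs A (occ 0.6) and B (occ 0.4); residue 3 lacks a CA
PDB_ALTLOC = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA AGLY A   2       5.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BGLY A   2       9.000   0.000   0.000  0.40  0.00           C
ATOM      4  N   SER A   3       1.000   1.000   1.000  1.00  0.00           N
ATOM      5  C   SER A   3       2.000   1.000   1.000  1.00  0.00           C
ATOM      6  O   SER A   3       3.000   1.000   1.000  1.00  0.00           O
ATOM      7  CA  LEU A   4       2.000   2.000   2.000  1.00  0.00           C
END
"""


@pytest.fixture
def pdb_3res(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(PDB_3RES)
    return p


@pytest.fixture
def pdb_altloc(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(PDB_ALTLOC)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
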