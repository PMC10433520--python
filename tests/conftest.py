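import numpy as np
import pytest

from corrdock import synthetic
from corrdock.structure_io import AtomRecord, Structure

MINIMAL_GLY = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      10.729   6.768  -4.123  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N  AGLY A   1       0.000   0.000   0.000  0.60  0.00           N
ATOM      2  N  BGLY A   1       9.000   0.000   0.000  0.40  0.00           N
ATOM      3  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      4  C   GLY A   1       2.100   1.300   0.000  1.00  0.00           C
END
"""

VINA_LOG = """\
Detected 4 CPUs
Using random seed: 1480304528

mode |   affinity | dist from best mode
     | (kcal/mol) | rmsd l.b.| rmsd u.b.
-----+------------+----------+----------
   1       -7.6      0.000      0.000
   2       -7.1      1.931      3.200
   3       -6.5      2.551      4.310

Writing output ... done.
"""

PDBQT_POSES = """\
MODEL 1
REMARK VINA RESULT:      -7.6      0.000      0.000
ROOT
ATOM      1  C1  LIG     1       1.234   2.345   3.456  0.00  0.00    +0.10 C\x20
ATOM      2  O1  LIG     1       2.500   2.345   3.456  0.00  0.00    -0.25 OA
ENDROOT
TORSDOF 3
ENDMDL
MODEL 2
REMARK VINA RESULT:      -6.9      1.800      2.900
ROOT
ATOM      1  C1  LIG     1       4.000   2.000   3.000  0.00  0.00    +0.10 C\x20
ATOM      2  O1  LIG     1       5.250   2.000   3.000  0.00  0.00    -0.25 OA
ENDROOT
TORSDOF 3
ENDMDL
"""


@pytest.fixture
def minimal_gly(tmp_path):
    path = tmp_path / "gly.pdb"
    path.write_text(MINIMAL_GLY)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture
def vina_log():
    return VINA_LOG


@pytest.fixture
def pdbqt_poses():
    return PDBQT_POSES


@pytest.fixture
def chain10():
    return synthetic.synth_chain(10)


def make_structure(atom_specs):
    """Structure from (name, element, resname, chain, resid, xyz) tuples."""
    return Structure(
        AtomRecord(i + 1, name, element, resname, chain, resid, np.asarray(xyz, float))
        for i, (name, element, resname, chain, resid, xyz) in enumerate(atom_specs)
    )
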