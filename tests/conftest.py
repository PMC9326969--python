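import numpy as np
import pytest

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       3.000   0.000   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   GLY A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.000   1.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.000   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       3.000   1.000   0.000  1.00  0.00           O
ENDMDL
"""


@pytest.fixture
def two_model_pdb(tmp_path):
    path = tmp_path / "two_model.pdb"
    path.write_text(TWO_MODEL_PDB)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
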