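"""Shared fixtures: toy structure files, small graphs, and the one trained
desk-scale model reused by the training/attribution/hotspot tests."""

import numpy as np
import pytest

import eqscore as eq
from eqscore.synthetic import SyntheticSpec, generate_pose_dataset

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  O   ALA A   1       2.100   1.100   0.300  1.00  0.00           O
END
"""

TOY_PDB_WITH_H = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  H   ALA A   1       0.500   0.900   0.100  1.00  0.00           H
ATOM      4  O   ALA A   1       2.100   1.100   0.300  1.00  0.00           O
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""

TOY_SDF = """\
toy
  manual

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.5000    0.5000    0.5000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.9000    0.5000    0.5000 N   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
$$$$
"""

TOY_SDF_WITH_H = """\
toy-h
  manual

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.5000    0.5000    0.5000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.9000    0.5000    0.5000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.4000    0.5000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
$$$$
"""


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


@pytest.fixture
def toy_files(tmp_path):
    return {
        "pdb": _write(tmp_path, "toy.pdb", TOY_PDB),
        "pdb_h": _write(tmp_path, "toy_h.pdb", TOY_PDB_WITH_H),
        "pdb_water": _write(tmp_path, "water.pdb", WATER_ONLY_PDB),
        "sdf": _write(tmp_path, "toy.sdf", TOY_SDF),
        "sdf_h": _write(tmp_path, "toy_h.sdf", TOY_SDF_WITH_H),
    }


def random_complex(rng, n_ligand=5, n_protein=20, span=8.0):
    """A random atom cloud (no planted structure) for geometry oracles."""
    from eqscore.structures_io import AtomRecord, Complex

    elements = ["C", "N", "O", "S"]
    atoms = []
    for i in range(n_ligand + n_protein):
        is_ligand = i < n_ligand
        atoms.append(AtomRecord(
            atom_id=i, element=elements[rng.integers(len(elements))],
            position=tuple(rng.uniform(-span, span, size=3)),
            is_ligand=is_ligand,
            residue_name="" if is_ligand else "UNK",
            residue_index=-1 if is_ligand else i,
            chain="" if is_ligand else "A",
            atom_name=f"X{i}",
            hbond_role="none"))
    return Complex(f"random-{rng.integers(1 << 30)}", atoms)


def rigid_motion(rng, reflect=False):
    """Random rotation (optionally improper) and translation."""
    matrix = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(matrix)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    if reflect:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-10, 10, size=3)


@pytest.fixture(scope="session")
def desk_config():
    return eq.ModelConfig.desk(seed=0)


@pytest.fixture(scope="session")
def pose_dataset():
    spec = SyntheticSpec()
    examples, complexes, truths = generate_pose_dataset(spec, 200, seed=11)
    return examples, complexes, truths


@pytest.fixture(scope="session")
def trained_pose_model(desk_config, pose_dataset):
    """The desk-scale pose classifier shared across downstream tests."""
    from eqscore.training import TrainConfig, train_pose_classifier

    examples, _, _ = pose_dataset
    params, history = train_pose_classifier(
        examples, desk_config, TrainConfig(epochs=80, seed=0))
    return params, history


@pytest.fixture(scope="session")
def synthetic_graph():
    from eqscore.synthetic import generate_complex

    complex_, truth = generate_complex(SyntheticSpec(seed=5))
    return eq.featurize(complex_), complex_, truth
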