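import numpy as np
import pytest

from rotormech import fixtures


def pdb_atom_line(serial, name, resname, chain, resid, x, y, z,
                  occ=1.0, b=0.0, element="C", altloc=" ", record="ATOM"):
    return (f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}"
            f"{resid:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2}")


@pytest.fixture(scope="session")
def two_residue_pdb():
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0),
        pdb_atom_line(3, "C", "ALA", "A", 1, 2.5, 1.0, 0.0),
        pdb_atom_line(4, "O", "ALA", "A", 1, 2.5, 2.2, 0.0, element="O"),
        pdb_atom_line(5, "N", "GLY", "A", 2, 3.7, 0.6, 0.0, element="N"),
        pdb_atom_line(6, "CA", "GLY", "A", 2, 4.8, 1.5, 0.0),
        pdb_atom_line(7, "C", "GLY", "A", 2, 6.1, 0.8, 0.0),
        pdb_atom_line(8, "O", "GLY", "A", 2, 6.2, -0.4, 0.0, element="O"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def altloc_pdb():
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.6, altloc="A"),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, occ=0.4, altloc="B"),
        pdb_atom_line(3, "CA", "ALA", "A", 2, 3.8, 0.0, 0.0),
        pdb_atom_line(4, "CA", "ALA", "A", 3, 7.6, 0.0, 0.0),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def multi_model_pdb():
    blocks = []
    for m in range(1, 4):
        blocks.append(f"MODEL     {m:>4}")
        for r in range(1, 4):
            blocks.append(pdb_atom_line(r, "CA", "ALA", "A", r,
                                        3.8 * (r - 1), float(m), 0.0))
        blocks.append("ENDMDL")
    blocks.append("END")
    return "\n".join(blocks) + "\n"


@pytest.fixture(scope="session")
def hetero_pdb():
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom_line(2, "CA", "ALA", "A", 2, 3.8, 0.0, 0.0),
        # modified residue with a Calpha: kept
        pdb_atom_line(3, "CA", "MSE", "A", 3, 7.6, 0.0, 0.0, record="HETATM"),
        # water and a free ligand without Calpha: dropped
        pdb_atom_line(4, "O", "HOH", "A", 101, 20.0, 0.0, 0.0,
                      element="O", record="HETATM"),
        pdb_atom_line(5, "C1", "LIG", "A", 102, 25.0, 0.0, 0.0,
                      record="HETATM"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def gaussian_hinge_gt():
    return fixtures.HingeGroundTruth(
        segment_lengths=(36, 36),
        hinges=(fixtures.HingeSpec(bend_sigma=10.0, twist_sigma=6.0),),
        seed=101,
    )


@pytest.fixture(scope="session")
def gaussian_hinge_ensemble(gaussian_hinge_gt):
    ens, gt = fixtures.make_hinge_ensemble(gaussian_hinge_gt, n=4096, seed=101)
    return ens, gt


@pytest.fixture(scope="session")
def two_state_hinge_ensemble():
    gt = fixtures.HingeGroundTruth(
        segment_lengths=(36, 36),
        hinges=(fixtures.HingeSpec(bend_sigma=2.72, model="two_state",
                                   bend_delta=3.55),),
        seed=202,
    )
    ens, gt = fixtures.make_hinge_ensemble(gt, n=4096, seed=202)
    return ens, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
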