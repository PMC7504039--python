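import numpy as np
import pytest

from complementa.structio import Atom, Pose, PoseEnsemble


def make_atom(name="CA", xyz=(0, 0, 0), residue_seq=1, chain_id="A",
              residue_name="GLY", element=None, serial=1, is_sidechain=None):
    if element is None:
        element = name[0]
    if is_sidechain is None:
        is_sidechain = name not in ("N", "CA", "C", "O", "OXT")
    return Atom(
        serial=serial, name=name, element=element, residue_name=residue_name,
        residue_seq=residue_seq, chain_id=chain_id, xyz=np.asarray(xyz, float),
        is_sidechain=is_sidechain,
    )


@pytest.fixture
def two_chain_pose():
    """Minimal pose: one Gly on chain A, one Gly on chain B, 5 Å apart."""
    atoms = [
        make_atom("N", (-1.2, 0, 0.8), 1, "A", serial=1),
        make_atom("CA", (0, 0, 0), 1, "A", serial=2),
        make_atom("C", (1.2, 0, 0.8), 1, "A", serial=3),
        make_atom("O", (1.2, 0, 2.0), 1, "A", serial=4),
        make_atom("N", (-1.2, 5, 0.8), 1, "B", serial=5),
        make_atom("CA", (0, 5, 0), 1, "B", serial=6),
        make_atom("C", (1.2, 5, 0.8), 1, "B", serial=7),
        make_atom("O", (1.2, 5, 2.0), 1, "B", serial=8),
    ]
    return Pose(model_id=1, atoms=atoms)


@pytest.fixture
def two_chain_ensemble(two_chain_pose):
    return PoseEnsemble([two_chain_pose], ligand_chain="A", receptor_chain="B")
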