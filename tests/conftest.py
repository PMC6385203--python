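import numpy as np
import pytest

from rfamap.structure_io import Atom, Pose, Structure


def atom(serial, name, element, res_name, res_seq, chain, xyz, icode=""):
    return Atom(serial, name, element, res_name, res_seq, chain,
                np.asarray(xyz, float), icode)


@pytest.fixture
def trimer_structure():
    """Minimal trimeric receptor: the four box-center residues on three chains."""
    residues = [(236, "THR"), (278, "GLN"), (312, "ILE"), (380, "LYS")]
    atoms = []
    serial = 0
    rng = np.random.default_rng(42)
    for ci, chain in enumerate("ABC"):
        for rs, rn in residues:
            serial += 1
            atoms.append(atom(serial, "CA", "C", rn, rs, chain,
                              rng.uniform(0, 50, 3)))
    return Structure(atoms=atoms, id="trimer")


def pocket_directed_pose(template: Pose, depth: float, pose_id: str,
                         score: float = -8.0) -> Pose:
    """Rotate a template so its chain axis (+x) points into -z (pocket depth
    axis) and drop it ``depth`` Å below the mouth plane z=0."""
    rot = np.array([[0.0, 0.0, 1.0],
                    [0.0, 1.0, 0.0],
                    [-1.0, 0.0, 0.0]])
    return template.transformed(rot, np.array([0.0, 0.0, -depth]),
                                pose_id=pose_id, score=score)
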