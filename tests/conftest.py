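import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from acedock.core_model import Atom, ProteinStructure, RigidTransform


def random_transform(rng: np.random.Generator, max_shift: float = 10.0) -> RigidTransform:
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_matrix()
    return RigidTransform(R, rng.uniform(-max_shift, max_shift, 3))


def toy_structure(coords, chain="A", types=None, names=None, resseq=None) -> ProteinStructure:
    """Wrap raw coordinates in single-atom or grouped pseudo-residues."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    atoms = []
    for i, xyz in enumerate(coords):
        atoms.append(
            Atom(
                serial=i + 1,
                name=names[i] if names else "CA",
                element="C",
                residue_name="GLY",
                residue_seq=resseq[i] if resseq is not None else i + 1,
                insertion_code=" ",
                chain_id=chain,
                coords=xyz,
                ace_type=None if types is None else types[i],
            )
        )
    return ProteinStructure(atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
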