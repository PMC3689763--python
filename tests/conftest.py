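import numpy as np
import pytest

from ligandrmsd.synth_fixtures import (
    chain_ligand_spec,
    ring_tail_ligand_spec,
    spec_to_instance,
)


@pytest.fixture
def chain_instance():
    """Asymmetric 10-atom chain ligand (unique atom mapping)."""
    spec = chain_ligand_spec(10, comp_id="LIG", seed=11)
    return spec_to_instance(spec, pdb_id="TSTA")


@pytest.fixture
def chain_spec():
    return chain_ligand_spec(10, comp_id="LIG", seed=11)


@pytest.fixture
def ring_instance():
    """Benzamidine-like ligand with ring-flip symmetry."""
    return spec_to_instance(ring_tail_ligand_spec(), pdb_id="TSTB")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    from ligandrmsd.superpose import RigidTransform

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-10, 10, size=3)
    return RigidTransform(R, t)
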