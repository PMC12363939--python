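import numpy as np
import pytest

from structforge.fixtures import make_components, make_toy_peptide
from structforge.io import attach_intra_component_bonds


@pytest.fixture(scope="session")
def components():
    return make_components(0)


@pytest.fixture()
def peptide(components):
    """Five-residue helical peptide, bonds attached."""
    state, _ = make_toy_peptide("ACSAG", seed=0)
    return attach_intra_component_bonds(state, components)


@pytest.fixture()
def two_chain(components):
    """Two copies of a short peptide, 8 A apart, as chains A and B."""
    state, _ = make_toy_peptide("AAS", seed=0, chain_id="A")
    other, _ = make_toy_peptide("AAS", seed=0, chain_id="B")
    other.table.atoms[["x", "y", "z"]] += np.array([0.0, 8.0, 0.0])
    other.table.atoms["entity_id"] = 2
    state.table.add_atoms(other.table.atoms.drop(columns=["atom_uid"])
                          .to_dict("records"))
    return state


def random_rotation(rng):
    """Uniform proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
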