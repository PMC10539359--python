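import numpy as np
import pytest

from fablens import ToyFabSpec, build_toy_fab
from fablens.structure_io import ATOMIC_MASSES, AtomSet


def make_atoms(coords, elements=None, chain="A", residue_numbers=None,
               atom_names=None, residue_names=None, masses=None):
    """Hand-rolled AtomSet for small geometric fixtures."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = len(coords)
    if elements is None:
        elements = ["C"] * n
    if atom_names is None:
        atom_names = ["CA"] * n
    if residue_numbers is None:
        residue_numbers = np.arange(1, n + 1)
    if residue_names is None:
        residue_names = ["ALA"] * n
    if masses is None:
        masses = [ATOMIC_MASSES.get(e, 12.0) for e in elements]
    chains = [chain] * n if isinstance(chain, str) else list(chain)
    return AtomSet(
        atom_id=np.arange(1, n + 1),
        element=np.array(elements, object),
        atom_name=np.array(atom_names, object),
        residue_name=np.array(residue_names, object),
        residue_number=np.asarray(residue_numbers, int),
        insertion_code=np.array([""] * n, object),
        chain_id=np.array(chains, object),
        coords=coords,
        occupancy=np.ones(n),
        b_factor=np.zeros(n),
        mass=np.asarray(masses, float),
    )


@pytest.fixture(scope="session")
def toy_fab():
    """Standard 150°-elbow toy Fab used across modules."""
    return build_toy_fab(ToyFabSpec(designed_elbow=150.0, seed=42))


@pytest.fixture(scope="session")
def small_fab():
    """Smaller toy Fab for the more expensive SASA / SAXS tests."""
    return build_toy_fab(ToyFabSpec(atoms_per_domain=80, domain_radius=8.0,
                                    designed_elbow=150.0, seed=7))


def random_rotation(seed):
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
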