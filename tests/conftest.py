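import numpy as np
import pytest

from oddkit.molio import Atom, Bond, Molecule
from oddkit.perception import perceive_features

ELEMENTS = ["C", "C", "C", "N", "O", "S", "F", "Cl", "Br", "P"]


def random_molecule(rng: np.random.Generator, n_atoms: int | None = None) -> Molecule:
    """A random connected molecule with coordinates, charges and properties.

    Geometry is arbitrary (not chemically valid) — these molecules exercise
    the file-format round trips and graph algorithms, not the chemistry.
    """
    n = n_atoms or int(rng.integers(2, 25))
    atoms = [Atom(ELEMENTS[rng.integers(len(ELEMENTS))],
                  rng.uniform(-20, 20, 3).round(4),
                  charge=int(rng.choice([0, 0, 0, 0, 1, -1])))
             for _ in range(n)]
    bonds = []
    # random spanning tree keeps the graph connected
    for i in range(1, n):
        j = int(rng.integers(0, i))
        bonds.append(Bond(j, i, order=int(rng.choice([1, 1, 1, 2, 3]))))
    existing = {b.key() for b in bonds}
    for _ in range(int(rng.integers(0, max(1, n // 3)))):
        i, j = sorted(rng.choice(n, 2, replace=False).tolist())
        if (i, j) not in existing:
            bonds.append(Bond(i, j, order=1))
            existing.add((i, j))
    props = {f"tag{k}": str(rng.integers(1000)) for k in range(int(rng.integers(0, 3)))}
    return Molecule(atoms=atoms, bonds=bonds, name=f"rnd{rng.integers(10**6)}",
                    properties=props)


def featurize_pair(protein, ligand):
    return (perceive_features(protein, as_protein=True), perceive_features(ligand))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
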