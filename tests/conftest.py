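import numpy as np
import pytest

from deltasolv.core import MolecularSystem, SolventSpec, load_parameters
from deltasolv.fixtures import make_toy_system
from deltasolv.gbneck2 import GBNeck2Model


@pytest.fixture(scope="session")
def water():
    return SolventSpec("water", 78.5)


@pytest.fixture(scope="session")
def chloroform():
    return SolventSpec("chloroform", 4.81)


@pytest.fixture(scope="session")
def gb_water(water):
    return GBNeck2Model(water)


@pytest.fixture
def diatomic():
    return make_toy_system("diatomic")


@pytest.fixture
def chain6():
    return make_toy_system("chain-6", seed=4)


def random_system(seed: int, n: int = 4, spread: float = 2.0
                  ) -> MolecularSystem:
    """Small random parameterized molecule with well-separated atoms."""
    rng = np.random.default_rng(seed)
    elements = list(rng.choice(["H", "C", "N", "O"], size=n))
    while True:
        coords = rng.normal(scale=spread, size=(n, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        if n == 1 or d[~np.eye(n, dtype=bool)].min() > 0.9:
            break
    charges = rng.uniform(-0.6, 0.6, size=n)
    charges -= charges.mean()
    return load_parameters(MolecularSystem(elements, coords),
                           charges=charges, formal_charge=0.0)
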