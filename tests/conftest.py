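import numpy as np
import pytest

from mechstrain import build_toy_cluster, toy_cluster_calculator
from mechstrain.geom_io import AtomicStructure
from mechstrain.mechanochemistry import morse_diatomic_calculator


@pytest.fixture(scope="session")
def toy_cluster():
    """Ideal tetrahedral Fe(SCH3)4-like cluster and its bond list."""
    return build_toy_cluster()


@pytest.fixture(scope="session")
def toy_calc(toy_cluster):
    structure, bonds = toy_cluster
    return toy_cluster_calculator(structure, bonds)


@pytest.fixture(scope="session")
def morse_calc():
    """Morse Fe–S diatomic with the published parameters."""
    return morse_diatomic_calculator()


@pytest.fixture()
def diatomic_start():
    return AtomicStructure(("Fe", "S"), np.array([[0.0, 0.0, 0.0],
                                                  [0.0, 0.0, 2.5]]))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Uniform random rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
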