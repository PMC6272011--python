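import numpy as np
import pytest

from popshift.energy import EnergyParameters, make_grid_box
from popshift.synthetic import make_toy_complex


@pytest.fixture(scope="session")
def params():
    return EnergyParameters.default()


@pytest.fixture(scope="session")
def toy(params):
    """Certified toy complex: (receptor, ligand, tree, optimum pose, score)."""
    return make_toy_complex(p=params)


@pytest.fixture(scope="session")
def toy_box(toy, params):
    """Affinity grid over the toy pocket at the study grid spacing."""
    receptor, ligand, *_ = toy
    return make_grid_box(receptor, 0.375, (61, 61, 61), params,
                         ligand_types=set(ligand.atom_types))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
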