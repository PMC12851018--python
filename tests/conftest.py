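import numpy as np
import pytest

from nsepot import AtomicSystem, ModelConfig, NSEPotential, default_oracle


@pytest.fixture(scope="session")
def oracle():
    """Default surrogate oracle without electrostatics (pure Morse curves)."""
    return default_oracle(use_coulomb=False)


@pytest.fixture(scope="session")
def oracle_coulomb():
    return default_oracle(use_coulomb=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained model; conservation and symmetry do not depend on fit."""
    cfg = ModelConfig(elements=(1, 6, 7, 8), n_basis=8, embedding_dim=8,
                      hidden_dim=32, seed=7)
    return NSEPotential(cfg)


@pytest.fixture()
def h2():
    return AtomicSystem([1, 1], [[0.0, 0.0, 0.0], [0.741, 0.0, 0.0]])


@pytest.fixture()
def water():
    return AtomicSystem(
        [8, 1, 1],
        [[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.2399, 0.9266, 0.0]],
    )


@pytest.fixture()
def methyl_radical():
    return AtomicSystem(
        [6, 1, 1, 1],
        [[0.0, 0.0, 0.0], [1.079, 0.0, 0.0], [-0.539, 0.934, 0.0], [-0.539, -0.934, 0.0]],
        charge=0.0, multiplicity=2.0,
    )
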