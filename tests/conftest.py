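import numpy as np
import pytest

from erkdyn.simulate import SimConfig, default_layout, generate_dataset

T190 = np.arange(190) * 6.0


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def t190():
    return T190.copy()


@pytest.fixture(scope="session")
def small_dataset():
    """A 900-cell plate covering all five history archetypes, 3 replicates."""
    layout = default_layout(n_cells_per_well=30, replicates=3)
    return generate_dataset(layout, SimConfig(), seed=11)
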