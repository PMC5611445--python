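import numpy as np
import pytest

from regelscreen.motif_catalog import load_default_catalog
from regelscreen.reference_elements import build_templates, default_elements
from regelscreen.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def templates():
    return build_templates()


@pytest.fixture(scope="session")
def elements():
    return default_elements()


@pytest.fixture(scope="session")
def sim_result():
    """One default simulation shared by structural tests."""
    return simulate_dataset(SimConfig(seed=11))


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
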