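import numpy as np
import pytest

from mitotyper.mitomodel import LabeledAlignment, default_model
from mitotyper.mitosim import SimulationConfig, simulate


def make_alignment(seqs: dict[str, str], mitotypes=None, populations=None):
    """Tiny alignment helper: ids starting with 'T' default to TNP, others
    to ENA; population defaults to the mitotype."""
    ids = list(seqs)
    if mitotypes is None:
        mitotypes = {s: ("TNP" if s.upper().startswith("T") else "ENA") for s in ids}
    if populations is None:
        populations = dict(mitotypes)
    return LabeledAlignment(
        ids=ids, seqs=[seqs[s] for s in ids],
        mitotypes=mitotypes, populations=populations,
    )


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def dataset():
    """One default-parameter simulated dataset shared across tests."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def het_dataset():
    return simulate(SimulationConfig(seed=12, het_rate=0.001))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
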