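import logging

import numpy as np
import pytest

from haploweb.reads import superpose
from haploweb.simdata import SimulationConfig, simulate_dataset

logging.getLogger("haploweb").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """A 3-species benchmark dataset shared across read-only tests."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture()
def worked_example_reads():
    """The hand-checked length-variant pair: one 1-bp deletion."""
    return superpose("ACGTACGT", "ACGACGT")
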