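import numpy as np
import pandas as pd
import pytest

from bficomm.sequence_units import SequenceSet
from bficomm.synthetic_data import SimulationConfig, generate_sites, sites_to_metadata


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, reduced-scale survey for pipeline-level tests."""
    return SimulationConfig(
        n_sites=5,
        gamma_richness=40,
        depth=150,
        protein_length=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def sites(default_config):
    return generate_sites(default_config)


@pytest.fixture(scope="session")
def metadata(sites):
    return sites_to_metadata(sites)


def make_sequence_set(records, gene="test_gene") -> SequenceSet:
    """records: iterable of (sample_id, seq_id, nt)."""
    return SequenceSet(
        gene=gene,
        records=pd.DataFrame(records, columns=["sample_id", "seq_id", "nt"]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
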