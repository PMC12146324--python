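import numpy as np
import pytest

from lncsubloc import SyntheticConfig, feature_matrix, simulate_dataset
from lncsubloc.dataset import CYTOPLASM, assign_labels


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic benchmark (n=1000, seed 42), shared across tests."""
    seqs, table, truth = simulate_dataset(SyntheticConfig())
    return seqs, table, truth


@pytest.fixture(scope="session")
def sim_labels(default_sim):
    """id -> 0/1 label (1 = cytoplasm) for the default benchmark."""
    _, table, _ = default_sim
    records, _ = assign_labels(list(zip(table.gene_id, table.cnrci)), "CL1")
    return {r.gene_id: int(r.label == CYTOPLASM) for r in records}


@pytest.fixture(scope="session")
def sim_correlation_matrix(default_sim):
    seqs, _, _ = default_sim
    return feature_matrix(seqs, "correlation")


@pytest.fixture(scope="session")
def sim_composition_matrix(default_sim):
    seqs, _, _ = default_sim
    return feature_matrix(seqs, "composition")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
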