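import numpy as np
import pytest

from kcdta.model import featurize_pairs
from kcdta.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_records():
    """A small synthetic dataset shared by training-path tests."""
    records, truth = generate_dataset(
        SyntheticSpec(n_records=24, n_molecules=12, n_proteins=12,
                      seq_length_range=(30, 120), noise_sd=0.1, seed=11))
    return records, truth


@pytest.fixture(scope="session")
def tiny_data(tiny_records):
    records, _ = tiny_records
    return featurize_pairs(
        [r.smiles for r in records], [r.sequence for r in records],
        y=[r.affinity for r in records], branches=("tensor3d", "matrix2d"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
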