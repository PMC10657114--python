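import numpy as np
import pytest

from duplexgnn import SimulationConfig, generate_dataset
from duplexgnn.sequence_encoding import Corpus, Origin, train_cbow
from duplexgnn.training_eval import fit_embedding_tables
from duplexgnn.word2vec import CbowParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """60 balanced records with the default geometry."""
    return generate_dataset(SimulationConfig(n_pairs=60, rng_seed=3))


@pytest.fixture(scope="session")
def tiny_tables(small_dataset):
    """Quick low-epoch embedding tables for plumbing tests (not for learning)."""
    return fit_embedding_tables(small_dataset, CbowParams(epochs=3, seed=0))


@pytest.fixture(scope="session")
def fitted_table():
    """A properly fitted miRNA table on a small corpus."""
    sentences = [["ACG", "UAC", "GUA", "CGU"], ["UAC", "ACG", "GUA"],
                 ["CGU", "GUA", "ACG", "UAC"]] * 10
    return train_cbow(Corpus(sentences, Origin.MIRNA), epochs=20, seed=1)
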