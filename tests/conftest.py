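import numpy as np
import pytest

from kanbind.io_formats import DatasetManifest, EmbeddingTable, LabeledSequence
from kanbind.model import ModelConfig
from kanbind.simulate import SimSpec, make_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def identity_table():
    """A 2-token, 4-dimensional table with unit-vector rows."""
    return EmbeddingTable(dimension=4, vectors={
        "AAA": np.array([1.0, 0.0, 0.0, 0.0]),
        "AAC": np.array([0.0, 1.0, 0.0, 0.0]),
    })


def _random_seqs(n, length, label, rng, prefix):
    bases = rng.choice(list("ACGT"), size=(n, length))
    return [LabeledSequence(f"{prefix}_{i}", "".join(row), label)
            for i, row in enumerate(bases)]


@pytest.fixture()
def small_manifest(rng):
    """40 + 40 random 60-bp sequences (no signal)."""
    return DatasetManifest(
        positives=_random_seqs(40, 60, 1, rng, "pos"),
        negatives=_random_seqs(40, 60, 0, rng, "neg"),
        source="fixture")


@pytest.fixture(scope="session")
def tiny_config():
    """A scaled-down architecture for fast training tests."""
    return ModelConfig(conv_blocks=(3,), use_bilstm=True, bilstm_hidden=8,
                       fusion_dim=16, kan_hidden=4, dropout_rate=0.0,
                       sequence_length=50)


@pytest.fixture(scope="session")
def motif_dataset_small():
    """A small, clearly separable motif dataset (shared across tests)."""
    return make_dataset(SimSpec(n_pos=150, n_neg=150, length=50,
                                motif_strength=10.0, seed=7))
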