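import numpy as np
import pytest

from orrcnn.data_io import ProteinRecord, ScoredPair
from orrcnn.embeddings import eh_table, onehot_table
from orrcnn.encoder import RCNNConfig, EncoderState
from orrcnn.ordinal_head import IntervalPartition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Encoder small enough for fast unit tests."""
    return RCNNConfig(num_units=2, kernel_width=3, hidden_dim=6, pool_width=3, in_dim=7)


@pytest.fixture
def small_encoder(small_config):
    return EncoderState.init(small_config, seed=42)


@pytest.fixture
def partition20():
    return IntervalPartition(0.0, 1.0, 20)


@pytest.fixture
def tiny_records():
    return [
        ProteinRecord(id="P1", residues="MKVLAAGICDEFHNQRSTWY" * 3),
        ProteinRecord(id="P2", residues="ACDEFGHIKLMNPQRSTVWY" * 4),
        ProteinRecord(id="P3", residues="AAAAGGGGVVVV" * 5),
    ]


def labeled_pairs(scores, partition):
    from orrcnn.ordinal_head import assign_labels

    pairs = [ScoredPair(id1=f"a{i}", id2=f"b{i}", score=s) for i, s in enumerate(scores)]
    return assign_labels(pairs, partition)
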