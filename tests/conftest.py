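import numpy as np
import pytest

from ppii.dataset import make_all_windows, split, undersample_balance
from ppii.fixtures import MotifSpec, make_labeled_sequences
from ppii.model import CNNConfig, EncoderConfig


@pytest.fixture(scope="session")
def tiny_encoder():
    return EncoderConfig.tiny()


@pytest.fixture(scope="session")
def tiny_cnn():
    return CNNConfig.tiny()


@pytest.fixture(scope="session")
def motif_sequences_small():
    """~120 sequences with the default five-fold proline-enriched motif."""
    return make_labeled_sequences(MotifSpec(n_sequences=120, seed=5))


@pytest.fixture(scope="session")
def balanced_split_small(motif_sequences_small):
    windows = make_all_windows(motif_sequences_small, 15)
    balanced = undersample_balance(windows, seed=7)
    return split(balanced, "balanced_4to1", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
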