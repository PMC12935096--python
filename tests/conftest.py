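import numpy as np
import pytest

from fragforge.fixtures import make_fixture, make_fixture_set
from fragforge.fragmenter import fragment_complex
from fragforge.network import ModelConfig, TrainConfig


@pytest.fixture(scope="session")
def ethylbenzene_entry():
    return make_fixture(1, 50, "CCc1ccccc1")


@pytest.fixture(scope="session")
def fixture_entries():
    """A dozen synthetic complexes across three protein families."""
    return make_fixture_set(3, 12)


@pytest.fixture(scope="session")
def fixture_examples(fixture_entries):
    out = []
    for e in fixture_entries:
        out.extend(fragment_complex(e))
    return out


@pytest.fixture(scope="session")
def fixture_receptors(fixture_entries):
    return {e.entry_id: e.receptor for e in fixture_entries}


@pytest.fixture(scope="session")
def small_model_config():
    """A narrow network for mechanics tests; full width is exercised in the
    shape-contract and learnability tests."""
    return ModelConfig(conv_channels=4, embedding_dim=16)


@pytest.fixture(scope="session")
def fast_train_config():
    return TrainConfig(epochs=3, batch_size=8, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
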