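import numpy as np
import pytest

from ffinet.model import FFiNet, ModelConfig
from ffinet.molio import embed_conformer


@pytest.fixture(scope="session")
def ethanol():
    return embed_conformer("CCO", seed=7)


@pytest.fixture(scope="session")
def propane():
    return embed_conformer("CCC", seed=3)


@pytest.fixture(scope="session")
def butane():
    return embed_conformer("CCCC", seed=3)


@pytest.fixture(scope="session")
def benzene():
    return embed_conformer("c1ccccc1", seed=5)


@pytest.fixture(scope="session")
def feat_dim(ethanol):
    return ethanol.atom_features.shape[1]


@pytest.fixture
def small_model(feat_dim):
    def factory(**overrides):
        kwargs = dict(hidden_dim=16, n_heads=2, n_layers=2, dropout=0.0, seed=0)
        kwargs.update(overrides)
        cfg = ModelConfig(**kwargs)
        return FFiNet(cfg, feat_dim)

    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
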