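import numpy as np
import pytest

from cecsclip.experiments import build_toy_corpus, pretrain_encoder
from cecsclip.knowledge import build_knowledge_base
from cecsclip.scenes import SceneSpec, default_catalog, generate_dataset


@pytest.fixture(scope="session")
def catalog3():
    return default_catalog(3)


@pytest.fixture(scope="session")
def kb3(catalog3):
    return build_knowledge_base(catalog3, seed=0)


@pytest.fixture(scope="session")
def scenes_small(catalog3):
    """20 small scenes for fast unit tests."""
    return generate_dataset(
        catalog3, 20, SceneSpec(width=96, height=96, n_targets=3, rng_seed=0), seed=0
    )


@pytest.fixture(scope="session")
def toy_corpus():
    """The full toy study conditions (3 species, 200 scenes, 70/15/15)."""
    return build_toy_corpus(seed=0)


@pytest.fixture(scope="session")
def pretrained_encoder(toy_corpus):
    _, kb, train, _, _ = toy_corpus
    return pretrain_encoder(kb, train, seed=0)


@pytest.fixture(scope="session")
def trained_cecs(toy_corpus, pretrained_encoder):
    """One trained full model, shared by the slower behavioural tests."""
    from cecsclip.experiments import train_variant

    _, kb, train, _, _ = toy_corpus
    return train_variant("cecs", kb, train, seed=0, encoder_init=pretrained_encoder)
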