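import logging

import pytest
from hypothesis import settings

from phitag.synthetic import GeneratorConfig, generate_corpus

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # keep expected per-operation warnings out of the test output but
    # still capturable via caplog in the tests that assert on them
    logging.getLogger("phitag").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def small_corpus():
    """20 clean (typo-free) site_A notes."""
    return generate_corpus(
        GeneratorConfig(n_notes=20, seed=11, typo_rate=0.0), "site_A")


@pytest.fixture(scope="session")
def typo_corpus():
    """30 site_A notes with run-together-word typos injected."""
    return generate_corpus(
        GeneratorConfig(n_notes=30, seed=12, typo_rate=0.15), "site_A")


def tiny_tagger(**overrides):
    """A small-dimension tagger configuration for fast tests."""
    from phitag.model.tagger import PhiTagger
    kwargs = dict(word_dim=16, char_dim=6, char_lstm_out=6,
                  word_lstm_out=12, semantic_feat_dim=6, lexical_feat_dim=4,
                  epochs=3, seed=5)
    kwargs.update(overrides)
    return PhiTagger(**kwargs)
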