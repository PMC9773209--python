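import numpy as np
import pytest

from speechrestore import (GatingSpec, SentenceSpec, build_noise_model,
                           synth_sentence)


@pytest.fixture(scope="session")
def sentence_corpus():
    """Five synthetic sentences at 16 kHz (shared, read-only)."""
    return [synth_sentence(SentenceSpec(seed=i))[0] for i in range(5)]


@pytest.fixture(scope="session")
def noise_model(sentence_corpus):
    return build_noise_model(sentence_corpus)


@pytest.fixture
def gating_spec():
    return GatingSpec(rate_hz=2.0, duty=0.5, start_phase="speech_first", ramp_ms=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
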