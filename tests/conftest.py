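import numpy as np
import pytest

from lazyvwfa.lexicon import generate_lexicon
from lazyvwfa.training import RegimeConfig, train_to_criterion


@pytest.fixture(scope="session")
def lex20():
    return generate_lexicon(20, 0, seed=42)


@pytest.fixture(scope="session")
def trained_small(lex20):
    """One small network trained to the central-location criterion."""
    return train_to_criterion(lex20, RegimeConfig(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
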