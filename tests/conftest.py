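import numpy as np
import pytest

from sgatt.fcs import FCSVocabulary, mine_vocabulary
from sgatt.fixtures import FixtureSpec, enumerate_pool
from sgatt.knowledge import build_knowledge_base


@pytest.fixture(scope="session")
def kb():
    return build_knowledge_base()


@pytest.fixture(scope="session")
def smiles_pool():
    """All distinct molecules from the synthetic generator (deterministic)."""
    return enumerate_pool(FixtureSpec())


@pytest.fixture(scope="session")
def pool_vocab(smiles_pool):
    return mine_vocabulary(smiles_pool, min_freq=3, max_token_len=8, max_vocab=256)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def chars_only_vocab(corpus) -> FCSVocabulary:
    """Vocabulary of single characters only (no mined merges, no units)."""
    tokens: dict[str, int] = {}
    for s in corpus:
        for ch in s:
            tokens[ch] = tokens.get(ch, 0) + 1
    return FCSVocabulary(tokens=tokens, min_freq=1, max_token_len=1)
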