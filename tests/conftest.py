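import datetime as dt

import numpy as np
import pytest

from cowordcast.corpus_io import DocumentRecord, TokenizedDocument
from cowordcast.synthetic import TrendScenario, generate_corpus, generate_tensor


def make_tokenized(doc_id, tokens, year=2001, month=3):
    return TokenizedDocument(doc_id=str(doc_id), date=dt.date(year, month, 1), tokens=tuple(tokens))


@pytest.fixture
def small_scenario():
    return TrendScenario(k_ai=4, k_bio=5, bins=4, base_rate=2.0, seed=3, spatial_corr=0.3, pair_jitter=0.5)


@pytest.fixture
def small_corpus(small_scenario):
    docs, tensor, lam = generate_corpus(small_scenario)
    return docs, tensor, lam


@pytest.fixture
def interchangeable_corpus():
    """Corpus where 'foo' and 'bar' appear only in byte-identical contexts."""
    docs = []
    for n in range(200):
        tok = "foo" if n % 2 == 0 else "bar"
        docs.append(make_tokenized(n, ("north", "south", tok, "east", "west")))
    for n in range(200, 260):
        docs.append(make_tokenized(n, ("alpha", "beta", "gamma", "delta")))
    return docs


@pytest.fixture
def random_tensor():
    tensor, _ = generate_tensor(TrendScenario(k_ai=5, k_bio=6, bins=4, base_rate=3.0, seed=11, pair_jitter=0.8))
    return tensor
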