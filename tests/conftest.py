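"""Shared fixtures: a small synthetic world reused across module tests.

The world is deliberately smaller than the package's default synthetic
corpus so unit tests stay fast; tests that need the full desk-scale world
build it themselves.
"""

import numpy as np
import pytest

from pkword2vec import (
    SyntheticSpec,
    build_prior_source,
    build_vocabulary,
    generate_corpus,
    generate_prior,
)
from pkword2vec.corpus import MEDICAL, NON_MEDICAL


SMALL_SPEC = SyntheticSpec(
    vocab_size=120,
    n_clusters=8,
    cluster_size=4,
    n_docs=150,
    doc_length=30,
    seed=7,
)


@pytest.fixture(scope="session")
def small_world():
    corpus = generate_corpus(SMALL_SPEC)
    vocab = build_vocabulary(corpus.docs, corpus.lexicon)
    prior_map = generate_prior(SMALL_SPEC, corpus)
    sources = [
        build_prior_source(prior_map, vocab, NON_MEDICAL, name="toy-general"),
        build_prior_source(prior_map, vocab, MEDICAL, name="toy-medical"),
    ]
    return {
        "spec": SMALL_SPEC,
        "corpus": corpus,
        "vocab": vocab,
        "prior_map": prior_map,
        "sources": sources,
    }


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(1234))
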