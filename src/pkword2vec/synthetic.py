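"""Synthetic corpora with planted semantic structure.

Real patient-portal message corpora are access-restricted, so every other
module is exercised on generated data that reproduces the statistical shape
of that setting at desk scale: a Zipf-distributed vocabulary of a few
hundred words, short documents, a ~80/20 non-medical/medical word
partition, planted synonym clusters whose members co-occur more often than
chance, and a toy "pre-trained" embedding that covers only part of the
vocabulary (words outside it emulate the no-prior-knowledge case).

Cluster co-occurrence is induced by a mixture process: each document
activates a small set of clusters, and every token is drawn from the Zipf
marginal reweighted by ``boost`` on the active clusters' members.  With
``boost = 1`` the corpus is exactly the null Zipf model; larger values
raise within-cluster co-occurrence while leaving the marginal close to
Zipf.  All outputs are deterministic functions of the spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import MEDICAL, NON_MEDICAL
from .evaluation import ComparisonTask

__all__ = [
    "SyntheticSpec",
    "generate_corpus",
    "generate_prior",
    "generate_votes",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Defaults describe the standard desk-scale world used throughout the
    test suite: 300 words, 20 planted clusters of 5, 500 documents of 50
    tokens, a five-fold within-cluster co-occurrence boost, the 80/20
    non-medical/medical split of the motivating corpus, and a toy prior
    covering 70% of each category with mild noise.
    """

    vocab_size: int = 300
    n_clusters: int = 20
    cluster_size: int = 5
    zipf_exponent: float = 1.05
    n_docs: int = 500
    doc_length: int = 50
    boost: float = 5.0
    medical_fraction: float = 0.2
    prior_coverage: float = 0.7
    prior_noise: float = 0.1
    dim_prior: int = 32
    n_active_clusters: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters * self.cluster_size > self.vocab_size:
            raise ValueError("clusters do not fit in the vocabulary")
        if not (0 <= self.medical_fraction <= 1
                and 0 <= self.prior_coverage <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if min(self.vocab_size, self.n_clusters, self.cluster_size,
               self.doc_length, self.dim_prior) < 1 or self.n_docs < 1:
            raise ValueError("sizes must be positive")
        if self.boost < 1 or self.prior_noise < 0 or self.zipf_exponent <= 0:
            raise ValueError("boost >= 1, prior_noise >= 0, zipf_exponent > 0")


@dataclass
class SyntheticCorpus:
    """Generated documents plus the ground truth needed for scoring."""

    docs: list[list[str]]
    cluster_of: dict[str, int]          # word -> cluster id (-1: unclustered)
    lexicon: dict[str, str]             # word -> category
    words: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.words = sorted(self.cluster_of)

    def cluster_mates(self, word: str) -> set[str]:
        c = self.cluster_of[word]
        if c < 0:
            return set()
        return {w for w, ci in self.cluster_of.items()
                if ci == c and w != word}

    def save(self, corpus_path: str | Path, lexicon_path: str | Path,
             truth_path: str | Path) -> None:
        with open(corpus_path, "w", encoding="utf-8") as fh:
            for doc in self.docs:
                fh.write(" ".join(doc) + "\n")
        with open(lexicon_path, "w", encoding="utf-8") as fh:
            for w in self.words:
                fh.write(f"{w}\t{self.lexicon[w]}\n")
        pd.DataFrame(
            {"word": self.words,
             "cluster": [self.cluster_of[w] for w in self.words],
             "category": [self.lexicon[w] for w in self.words]}
        ).to_csv(truth_path, sep="\t", index=False)


def _rngs(spec: SyntheticSpec, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(spec.seed).spawn(n)
    return [np.random.Generator(np.random.PCG64(c)) for c in children]


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Sample documents with Zipf marginals and planted synonym clusters.

    Words ``w000 .. w{V-1}`` have Zipf weight ``(rank + 1) ** -s``.
    Cluster membership is a random subset of the vocabulary (so clusters
    span the whole frequency range); a random ``medical_fraction`` of words
    is labeled medical.
    """
    V = spec.vocab_size
    words = [f"w{i:03d}" for i in range(V)]
    zipf = (np.arange(1, V + 1, dtype=np.float64)) ** (-spec.zipf_exponent)
    zipf /= zipf.sum()

    assign_rng, doc_rng = _rngs(spec, 2)
    perm = assign_rng.permutation(V)
    cluster_of = {w: -1 for w in words}
    clusters = []
    for c in range(spec.n_clusters):
        members = perm[c * spec.cluster_size : (c + 1) * spec.cluster_size]
        clusters.append(np.sort(members))
        for i in members:
            cluster_of[words[i]] = c
    n_med = int(round(spec.medical_fraction * V))
    med_ids = set(assign_rng.choice(V, size=n_med, replace=False).tolist())
    lexicon = {w: (MEDICAL if i in med_ids else NON_MEDICAL)
               for i, w in enumerate(words)}

    docs: list[list[str]] = []
    for _ in range(spec.n_docs):
        active = doc_rng.choice(spec.n_clusters,
                                size=min(spec.n_active_clusters,
                                         spec.n_clusters),
                                replace=False)
        weights = zipf.copy()
        for c in active:
            weights[clusters[c]] *= spec.boost
        weights /= weights.sum()
        ids = doc_rng.choice(V, size=spec.doc_length, p=weights)
        docs.append([words[i] for i in ids])
    return SyntheticCorpus(docs, cluster_of, lexicon)


def generate_prior(spec: SyntheticSpec,
                   corpus: SyntheticCorpus) -> dict[str, np.ndarray]:
    """Build the toy pre-trained embedding aligned with the planted clusters.

    Each cluster gets a random unit centroid in ``dim_prior`` dimensions;
    member vectors are the centroid plus Gaussian noise of scale
    ``prior_noise``, renormalized.  Unclustered words get independent
    random unit vectors.  Within each category, only a ``prior_coverage``
    fraction of words receives a vector — the rest emulate
    out-of-pre-trained-vocabulary words without prior knowledge.  The
    dimension is deliberately unrelated to the trained dimension: prior
    sources of any vector size are usable.
    """
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([spec.seed, 17])))
    d = spec.dim_prior

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    centroids = {c: unit(rng.standard_normal(d))
                 for c in range(spec.n_clusters)}
    vectors: dict[str, np.ndarray] = {}
    for w in corpus.words:
        c = corpus.cluster_of[w]
        if c >= 0:
            vectors[w] = unit(centroids[c]
                              + spec.prior_noise * rng.standard_normal(d))
        else:
            vectors[w] = unit(rng.standard_normal(d))

    covered: dict[str, np.ndarray] = {}
    for category in (NON_MEDICAL, MEDICAL):
        cat_words = [w for w in corpus.words
                     if corpus.lexicon[w] == category]
        n_cov = int(round(spec.prior_coverage * len(cat_words)))
        take = rng.choice(len(cat_words), size=n_cov, replace=False)
        for i in np.sort(take):
            covered[cat_words[i]] = vectors[cat_words[i]]
    return covered


def generate_votes(tasks: Sequence[ComparisonTask], p: float,
                   votes_per_task: int, seed: int = 0) -> pd.DataFrame:
    """Simulate reviewers: each vote independently prefers the regularized
    model's group with probability ``p``, mapped through the task's hidden
    A/B assignment."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if votes_per_task < 1:
        raise ValueError("votes_per_task must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    rows = []
    for t in tasks:
        prefers_pk = rng.random(votes_per_task) < p
        for r, pref in enumerate(prefers_pk):
            choice = ("a" if pref else "b") if t.a_is_pk else ("b" if pref else "a")
            rows.append({"task_id": t.task_id,
                         "reviewer_id": f"r{r:03d}",
                         "choice": choice})
    return pd.DataFrame(rows)
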