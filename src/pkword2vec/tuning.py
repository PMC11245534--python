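"""Hyperparameter selection by matching similarity distributions.

Word-pair benchmarks are unreliable on a small corpus, so the embedding
size ``d`` and the prior weight ``alpha`` are chosen by comparing
*similarity distributions*: for every vocabulary word, pool its cosine
similarities to its ``k`` (default 10) most similar words; the resulting
empirical distribution is a fingerprint of embedding geometry.

* ``d`` is chosen to minimize the 1-D Wasserstein distance between the
  baseline SGNS model's similarity distribution and that of a large
  reference model (e.g. a news-corpus word2vec), both restricted to their
  shared vocabulary.

* ``alpha`` is chosen so that the similarity distributions of the low-,
  mid- and high-frequency word tertiles agree with each other: the score is
  the mean of the three pairwise Wasserstein distances, with the variance
  of the three as tie-break.  Distances to the reference model per tertile
  are reported as diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Vocabulary
from .prior import PriorSource
from .trainer import TrainConfig, train
from .vectors import WordVectors

__all__ = [
    "SimilarityDistribution",
    "similarity_distribution",
    "frequency_tertiles",
    "wasserstein_1d",
    "bimodality_coefficient",
    "select_dimension",
    "select_alpha",
]

STRATA = ("low", "mid", "high")


@dataclass
class SimilarityDistribution:
    """Pooled top-``k`` cosine scores of one model (optionally one tertile)."""

    scores: np.ndarray
    k: int = 10
    stratum: str = "all"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.size == 0:
            raise ValueError("empty similarity distribution")


def _topk_scores(unit: np.ndarray, query_rows: np.ndarray, k: int,
                 chunk: int = 512) -> np.ndarray:
    """Top-``k`` cosines of each query row against all rows (self excluded)."""
    out = np.empty((len(query_rows), k))
    for start in range(0, len(query_rows), chunk):
        rows = query_rows[start : start + chunk]
        sims = unit[rows] @ unit.T
        sims[np.arange(len(rows)), rows] = -np.inf
        out[start : start + len(rows)] = -np.partition(-sims, k - 1,
                                                       axis=1)[:, :k]
    return out


def similarity_distribution(
    model: WordVectors,
    words: Sequence[str] | None = None,
    k: int = 10,
    stratum: str = "all",
    stratum_words: Sequence[str] | None = None,
) -> SimilarityDistribution:
    """Pool every word's ``k`` highest cosines to the other words.

    ``words`` restricts the similarity universe (e.g. the vocabulary shared
    with a reference model); ``stratum_words`` further restricts which
    words' top-``k`` scores are pooled (neighbors still come from the full
    restriction), as when stratifying by frequency tertile.
    """
    restricted = model.restrict(list(words)) if words is not None else model
    n = len(restricted)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} words, got {n}")
    unit = restricted.unit()
    if stratum_words is None:
        query = np.arange(n)
    else:
        query = np.array([restricted.index[w] for w in stratum_words
                          if w in restricted.index], dtype=np.int64)
        if query.size == 0:
            raise ValueError(f"stratum {stratum!r} has no words in the model")
    scores = _topk_scores(unit, query, k)
    return SimilarityDistribution(scores.ravel(), k=k, stratum=stratum)


def frequency_tertiles(vocab: Vocabulary) -> dict[str, str]:
    """Partition words into low/mid/high frequency tertiles.

    Words are ordered by ascending count with word-id tie-break and split
    into three groups whose sizes differ by at most one (the remainder goes
    to the lower tertiles first).
    """
    n = len(vocab)
    if n < 3:
        raise ValueError("need at least 3 words for tertiles")
    order = sorted(range(n), key=lambda i: (vocab.counts[i], i))
    sizes = [n // 3 + (1 if r < n % 3 else 0) for r in range(3)]
    labels: dict[str, str] = {}
    pos = 0
    for stratum, size in zip(STRATA, sizes):
        for i in order[pos : pos + size]:
            labels[vocab.words[i]] = stratum
        pos += size
    return labels


def wasserstein_1d(a: SimilarityDistribution | np.ndarray,
                   b: SimilarityDistribution | np.ndarray) -> float:
    """First Wasserstein distance between two empirical 1-D distributions.

    For equal sample sizes this equals the mean absolute difference of the
    sorted samples; in general it is the integral of the absolute CDF
    difference.
    """
    sa = a.scores if isinstance(a, SimilarityDistribution) else np.asarray(a)
    sb = b.scores if isinstance(b, SimilarityDistribution) else np.asarray(b)
    return float(stats.wasserstein_distance(sa, sb))


def bimodality_coefficient(scores: np.ndarray) -> float:
    """Sarle's bimodality coefficient ``(g1^2 + 1) / (g2 + 3(n-1)^2 /
    ((n-2)(n-3)))``; ~5/9 for a uniform, higher when two modes form."""
    x = np.asarray(scores, dtype=np.float64)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def _tertile_distributions(model: WordVectors, vocab: Vocabulary, k: int
                           ) -> dict[str, SimilarityDistribution]:
    labels = frequency_tertiles(vocab)
    out = {}
    for stratum in STRATA:
        words = [w for w in model.words if labels.get(w) == stratum]
        out[stratum] = similarity_distribution(
            model, k=k, stratum=stratum, stratum_words=words)
    return out


def select_dimension(
    docs: Sequence[Sequence[str]],
    vocab: Vocabulary,
    reference: WordVectors,
    grid: Sequence[int] = (10, 15, 25, 45, 70, 100, 150, 200, 300),
    config: TrainConfig = TrainConfig(),
    k: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the embedding size whose SGNS similarity distribution is
    closest (Wasserstein) to the reference model's.

    For each ``d`` in the grid a pure SGNS model (``alpha = 0``) is trained
    with the fixed seed; both distributions are computed over the shared
    vocabulary.  Returns the argmin and the full distance table.
    """
    shared = [w for w in vocab.words if w in reference.index]
    if len(shared) < k + 1:
        raise ValueError("reference shares too few words with the vocabulary")
    ref_dist = similarity_distribution(reference, words=shared, k=k)
    rows = []
    for d in grid:
        pair, _ = train(docs, vocab, priors=(),
                        config=config.with_(alpha=0.0, dim=int(d)))
        model = pair.word_vectors(vocab)
        dist = similarity_distribution(model, words=shared, k=k)
        rows.append({"d": int(d),
                     "wasserstein": wasserstein_1d(dist, ref_dist)})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["wasserstein"].idxmin(), "d"])
    return best, table


def select_alpha(
    docs: Sequence[Sequence[str]],
    vocab: Vocabulary,
    priors: Sequence[PriorSource],
    grid: Sequence[float] = (0.0, 1e-7, 1e-6, 5e-6, 1e-5, 1e-4),
    config: TrainConfig = TrainConfig(),
    reference: WordVectors | None = None,
    k: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Choose the prior weight that best balances embedding quality across
    word-frequency tertiles.

    For each ``alpha`` a model is trained with the fixed seed; the score is
    the mean pairwise Wasserstein distance among the three tertile
    similarity distributions, with the variance of the three as tie-break.
    When a reference model is supplied, per-tertile distances to it are
    added to the diagnostics table.
    """
    rows = []
    for a in grid:
        pair, _ = train(docs, vocab, priors=priors,
                        config=config.with_(alpha=float(a)))
        model = pair.word_vectors(vocab)
        dists = _tertile_distributions(model, vocab, k)
        pairwise = [
            wasserstein_1d(dists["low"], dists["mid"]),
            wasserstein_1d(dists["low"], dists["high"]),
            wasserstein_1d(dists["mid"], dists["high"]),
        ]
        row = {
            "alpha": float(a),
            "mean_pairwise": float(np.mean(pairwise)),
            "var_pairwise": float(np.var(pairwise)),
            "w_low_mid": pairwise[0],
            "w_low_high": pairwise[1],
            "w_mid_high": pairwise[2],
        }
        if reference is not None:
            shared = [w for w in vocab.words if w in reference.index]
            labels = frequency_tertiles(vocab)
            for stratum in STRATA:
                sw = [w for w in shared if labels[w] == stratum]
                ref_d = similarity_distribution(reference, words=shared,
                                                k=k, stratum_words=sw)
                mod_d = similarity_distribution(model, words=shared, k=k,
                                                stratum_words=sw)
                row[f"w_ref_{stratum}"] = wasserstein_1d(mod_d, ref_d)
        rows.append(row)
    table = pd.DataFrame(rows)
    order = table.sort_values(["mean_pairwise", "var_pairwise", "alpha"],
                              kind="stable")
    best = float(order.iloc[0]["alpha"])
    return best, table
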