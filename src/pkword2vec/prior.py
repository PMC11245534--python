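"""Prior knowledge extraction from pre-trained embedding sources.

A *prior source* is a pre-trained embedding (e.g. a general news-corpus
word2vec for non-medical words, a SNOMED-graph embedding for medical words)
restricted to the corpus vocabulary words of one category.  For every
covered word ``t`` the source defines a sampling distribution ``p_tj`` over
candidate words ``j``: candidates are the covered same-category words whose
pre-trained cosine similarity with ``t`` clears a threshold ``theta``, and
``p_tj`` is the softmax of the surviving cosines, so more similar words are
sampled more often.  ``theta`` is calibrated as the mean of the pooled
top-10 similarity scores among covered words.  Words whose candidate set is
empty (or that the source does not cover) have *no prior knowledge* and
contribute nothing to the prior-knowledge loss.

Candidate tables depend only on the fixed pre-trained space, so they are
precomputed once; during training the per-occurrence cost is a single
inverse-CDF draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .corpus import Vocabulary
from .vectors import WordVectors, normalize_rows

__all__ = [
    "PriorSource",
    "restrict_to_vocab",
    "calibrate_theta",
    "build_candidates",
    "build_prior_source",
    "sample_prior",
]


def restrict_to_vocab(
    pretrained: Mapping[str, np.ndarray] | WordVectors,
    vocab: Vocabulary,
    category: str | None = None,
) -> WordVectors:
    """Restrict a pre-trained embedding to the corpus vocabulary.

    Keeps the corpus words (optionally only those of one category) that the
    pre-trained source covers, in vocabulary-id order.
    """
    if isinstance(pretrained, WordVectors):
        pretrained = dict(zip(pretrained.words, pretrained.matrix))
    words = [
        w
        for i, w in enumerate(vocab.words)
        if w in pretrained
        and (category is None or vocab.categories[i] == category)
    ]
    if not words:
        raise ValueError("pre-trained source covers no vocabulary words")
    return WordVectors(words, np.array([pretrained[w] for w in words]))


def calibrate_theta(source: WordVectors, k: int = 10, chunk: int = 512) -> float:
    """Similarity threshold: mean of all pooled top-``k`` cosine scores.

    For each covered word, its ``k`` highest cosine similarities to the
    other covered words are collected; ``theta`` is the mean over the pooled
    scores.  Requires at least ``k + 1`` covered words.
    """
    n = len(source)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} covered words, got {n}")
    unit = source.unit()
    total = 0.0
    for start in range(0, n, chunk):
        sims = unit[start : start + chunk] @ unit.T
        rows = np.arange(start, min(start + chunk, n))
        sims[np.arange(len(rows)), rows] = -np.inf  # exclude self
        top = -np.partition(-sims, k - 1, axis=1)[:, :k]
        total += float(top.sum())
    return total / (n * k)


@dataclass
class PriorSource:
    """Candidate distributions ``p_tj`` for one pre-trained source.

    Attributes
    ----------
    name : str
        Label of the pre-trained source.
    category : str
        Vocabulary category this source covers.
    theta : float
        Cosine threshold below which a pair never qualifies.
    candidates : dict
        Vocabulary id ``t`` -> ``(ids, cos, p)`` arrays: candidate
        vocabulary ids, their pre-trained cosines (all ``>= theta``), and
        softmax probabilities summing to 1.  Words with an empty set are
        absent: they have no prior knowledge.
    """

    name: str
    category: str
    theta: float
    candidates: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    covered_ids: np.ndarray = field(init=False, repr=False)
    _cdf: dict[int, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.covered_ids = np.array(sorted(self.candidates), dtype=np.int64)
        self._cdf = {
            t: np.cumsum(p) for t, (_ids, _cos, p) in self.candidates.items()
        }

    def has_prior(self, word_id: int) -> bool:
        return word_id in self.candidates

    def n_covered(self) -> int:
        return len(self.candidates)

    def sample(self, word_id: int, rng: np.random.Generator) -> int | None:
        """Draw one candidate id with probability ``p_tj``; None if uncovered."""
        entry = self.candidates.get(word_id)
        if entry is None:
            return None
        ids, _cos, _p = entry
        j = np.searchsorted(self._cdf[word_id], rng.random(), side="right")
        return int(ids[min(j, len(ids) - 1)])

    def save(self, path: str | Path, vocab: Vocabulary) -> None:
        """Write the candidate table as (word, candidate, cosine, p) TSV."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# source={self.name}\tcategory={self.category}"
                     f"\ttheta={self.theta:.10g}\n")
            for t in sorted(self.candidates):
                ids, cos, p = self.candidates[t]
                for j, c, pj in zip(ids, cos, p):
                    fh.write(
                        f"{vocab.words[t]}\t{vocab.words[j]}\t{c:.8g}\t{pj:.8g}\n"
                    )


def build_candidates(
    source: WordVectors,
    vocab: Vocabulary,
    theta: float,
    name: str = "prior",
    category: str = "non-medical",
    chunk: int = 512,
) -> PriorSource:
    """Build per-word candidate distributions from a restricted source.

    For each covered word ``t`` the candidate set holds the covered words
    ``j != t`` with pre-trained cosine ``>= theta``; probabilities are the
    softmax over the surviving cosines only (normalization after
    thresholding).  Words with no survivor are recorded as having no prior
    knowledge.
    """
    unit = source.unit()
    vocab_ids = np.array([vocab.index[w] for w in source.words], dtype=np.int64)
    n = len(source)
    candidates: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for start in range(0, n, chunk):
        sims = unit[start : start + chunk] @ unit.T
        for r in range(sims.shape[0]):
            i = start + r
            row = sims[r]
            keep = np.flatnonzero(row >= theta)
            keep = keep[keep != i]
            if keep.size == 0:
                continue
            cos = row[keep]
            # stable ordering: descending cosine, vocabulary-id tie-break
            order = np.lexsort((vocab_ids[keep], -cos))
            keep, cos = keep[order], cos[order]
            ex = np.exp(cos - cos.max())
            p = ex / ex.sum()
            candidates[int(vocab_ids[i])] = (vocab_ids[keep], cos, p)
    return PriorSource(name=name, category=category, theta=theta,
                       candidates=candidates)


def build_prior_source(
    pretrained: Mapping[str, np.ndarray] | WordVectors,
    vocab: Vocabulary,
    category: str,
    name: str = "prior",
    theta: float | None = None,
    calibrate_on: str = "corpus",
    k: int = 10,
) -> PriorSource:
    """End-to-end construction: restrict, calibrate ``theta``, build ``p_tj``.

    ``calibrate_on`` selects the calibration universe: ``"corpus"`` uses the
    corpus-restricted vectors (the small-corpus default), ``"all"`` uses the
    whole pre-trained model.  An explicit ``theta`` skips calibration.
    """
    restricted = restrict_to_vocab(pretrained, vocab, category)
    if theta is None:
        if calibrate_on == "corpus":
            theta = calibrate_theta(restricted, k=k)
        elif calibrate_on == "all":
            full = (
                pretrained
                if isinstance(pretrained, WordVectors)
                else WordVectors.from_mapping(pretrained)
            )
            theta = calibrate_theta(full, k=k)
        else:
            raise ValueError(f"unknown calibration universe {calibrate_on!r}")
    return build_candidates(restricted, vocab, theta, name=name,
                            category=category)


def sample_prior(
    word_id: int, source: PriorSource, rng: np.random.Generator
) -> int | None:
    """Sample one prior-knowledge word for ``word_id`` (None if uncovered)."""
    return source.sample(word_id, rng)
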