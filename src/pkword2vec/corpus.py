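"""Corpus ingestion: token masking, vocabulary construction, word categories,
and the negative-sampling unigram distribution.

The target corpora are small collections of short clinical messages.  Raw
text goes through a masking pass that replaces spans of personally
identifying or numeric classes (URLs, email addresses, phone numbers,
timestamps, numerals) by class placeholder tokens such as ``<url>``, then is
lowercased and whitespace-tokenized with punctuation stripped from token
edges.  Masking is idempotent: running it over already-masked text is a
fixed point.

Each vocabulary word carries a category label, ``medical`` or
``non-medical``, supplied by a two-column lexicon file; unknown words
default to non-medical.  The category decides which pre-trained embedding
source provides a word's prior knowledge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MEDICAL",
    "NON_MEDICAL",
    "Vocabulary",
    "NegativeSamplingTable",
    "mask_tokens",
    "build_vocabulary",
    "negative_table",
    "read_corpus",
    "read_lexicon",
]

MEDICAL = "medical"
NON_MEDICAL = "non-medical"

_WRAPPED_PLACEHOLDER = re.compile(r"\W*(<[a-z]+>)\W*")

# Masking patterns, applied in order: more specific classes first so that a
# phone number is not consumed piecemeal by the numeral rule.
_MASK_RULES: list[tuple[str, re.Pattern[str]]] = [
    ("<url>", re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)),
    ("<email>", re.compile(r"\b[\w.+-]+@[\w-]+\.[\w.-]+\b")),
    (
        "<phone>",
        re.compile(
            r"(?:\+?1[-.\s]?)?(?:\(\d{3}\)\s?|\d{3}[-.\s])\d{3}[-.\s]\d{4}\b"
        ),
    ),
    (
        "<time>",
        re.compile(
            r"\b(?:\d{4}-\d{2}-\d{2}(?:[T\s]\d{2}:\d{2}(?::\d{2})?)?"  # ISO date/datetime
            r"|\d{1,2}/\d{1,2}/\d{2,4}"                                 # slash date
            r"|\d{1,2}:\d{2}(?::\d{2})?\s?(?:am|pm)?"                   # clock time
            r"|\d{1,2}\s?(?:am|pm))\b",
            re.IGNORECASE,
        ),
    ),
    ("<number>", re.compile(r"\b\d+(?:[.,]\d+)*\b")),
]

_EDGE_PUNCT = re.compile(r"^\W+|\W+$", re.UNICODE)


def mask_tokens(text: str) -> list[str]:
    """Mask sensitive/numeric spans and tokenize.

    URLs, email addresses, phone numbers, timestamps and numerals are each
    replaced by their class placeholder (``<url>``, ``<email>``, ``<phone>``,
    ``<time>``, ``<number>``); the remainder is lowercased and split on
    whitespace, with punctuation stripped from token edges.  Empty input
    yields an empty list.
    """
    for placeholder, pattern in _MASK_RULES:
        text = pattern.sub(placeholder, text)
    tokens: list[str] = []
    for raw in text.split():
        m = _WRAPPED_PLACEHOLDER.fullmatch(raw)
        if m:
            tokens.append(m.group(1))
            continue
        tok = _EDGE_PUNCT.sub("", raw).lower()
        if tok:
            tokens.append(tok)
    return tokens


def read_corpus(path: str | Path, *, mask: bool = True) -> list[list[str]]:
    """Read a one-document-per-line UTF-8 text file into token lists.

    Blank lines are skipped.  With ``mask=False`` the line is only
    lowercased and whitespace-split (for pre-tokenized corpora).
    """
    docs: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            docs.append(mask_tokens(line) if mask else line.lower().split())
    return docs


def read_lexicon(path: str | Path, *, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (word, category) delimited file into a dict."""
    lexicon: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            word, category = line.split(delimiter)[:2]
            lexicon[word] = category
    return lexicon


@dataclass
class Vocabulary:
    """Corpus word inventory with counts, categories and dense integer ids.

    Attributes
    ----------
    words : list of str
        Vocabulary in id order (ids are dense ``0..|V|-1``).
    counts : ndarray of int
        Token count per word over the retained corpus.
    categories : list of str
        ``medical`` or ``non-medical`` per word.
    total_tokens : int
        ``T``, the total retained token count; relative frequencies are
        ``counts / total_tokens``.
    """

    words: list[str]
    counts: np.ndarray
    categories: list[str]
    total_tokens: int
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.index = {w: i for i, w in enumerate(self.words)}
        if len(self.index) != len(self.words):
            raise ValueError("duplicate words in vocabulary")

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    @property
    def rel_freq(self) -> np.ndarray:
        """Relative frequency ``count / T`` per word; sums to 1."""
        return self.counts / self.total_tokens

    def ids(self, tokens: Sequence[str]) -> np.ndarray:
        """Map tokens to ids, silently dropping out-of-vocabulary tokens."""
        idx = self.index
        return np.fromiter(
            (idx[t] for t in tokens if t in idx), dtype=np.int64
        )

    def category_ids(self, category: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.categories) if c == category],
            dtype=np.int64,
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, w in enumerate(self.words):
                fh.write(f"{w}\t{i}\t{self.counts[i]}\t{self.categories[i]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        words, counts, cats = [], [], []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                w, _i, c, cat = line.rstrip("\n").split("\t")
                words.append(w)
                counts.append(int(c))
                cats.append(cat)
        counts_arr = np.asarray(counts, dtype=np.int64)
        return cls(words, counts_arr, cats, int(counts_arr.sum()))


def build_vocabulary(
    corpus: Iterable[Sequence[str]],
    lexicon: Mapping[str, str] | None = None,
    min_count: int = 1,
) -> Vocabulary:
    """Build a :class:`Vocabulary` from tokenized documents.

    Words seen fewer than ``min_count`` times are dropped; relative
    frequencies are computed over the retained tokens.  Words absent from
    ``lexicon`` default to ``non-medical``.  Ids are assigned by descending
    count with alphabetical tie-break, so id order is deterministic.
    """
    counts: dict[str, int] = {}
    n_docs = 0
    for doc in corpus:
        n_docs += 1
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    if n_docs == 0:
        raise ValueError("empty corpus")
    kept = {w: c for w, c in counts.items() if c >= min_count}
    if not kept:
        raise ValueError("all tokens filtered out: empty vocabulary")
    words = sorted(kept, key=lambda w: (-kept[w], w))
    lexicon = lexicon or {}
    cats = [lexicon.get(w, NON_MEDICAL) for w in words]
    count_arr = np.array([kept[w] for w in words], dtype=np.int64)
    return Vocabulary(words, count_arr, cats, int(count_arr.sum()))


@dataclass
class NegativeSamplingTable:
    """Unigram negative-sampling distribution ``P(w) ∝ count(w)^exponent``."""

    probs: np.ndarray
    exponent: float

    def sample(self, rng: np.random.Generator, size: int | tuple) -> np.ndarray:
        return rng.choice(len(self.probs), size=size, p=self.probs)


def negative_table(vocab: Vocabulary, exponent: float = 0.75) -> NegativeSamplingTable:
    """Build the smoothed unigram distribution used to draw negative samples.

    ``exponent=0.75`` is the standard smoothing of skip-gram negative
    sampling; ``exponent=1`` recovers the raw relative frequencies.
    """
    if exponent < 0:
        raise ValueError(f"exponent must be nonnegative, got {exponent}")
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    weights = vocab.counts.astype(np.float64) ** exponent
    return NegativeSamplingTable(weights / weights.sum(), exponent)
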