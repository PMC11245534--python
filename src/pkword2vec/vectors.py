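"""Reading and writing word vectors in the standard word2vec formats, plus
cosine-similarity primitives shared across the package.

The text format is a header line ``"<count> <dim>"`` followed by one row per
word: the word, then ``dim`` whitespace-separated floats.  The binary format
uses the same ASCII header, then for each word the word bytes, a single
space, and ``dim`` little-endian float32 values (optionally followed by a
newline, which this reader tolerates).  Both dialects interoperate with the
original C tool and with gensim's ``KeyedVectors``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "load_word2vec",
    "save_word2vec",
    "cosine",
    "normalize_rows",
    "WordVectors",
]


def load_word2vec(path: str | Path, binary: bool | None = None) -> dict[str, np.ndarray]:
    """Load a word2vec-format vector file into a word -> vector dict.

    Parameters
    ----------
    path : path
        File in word2vec text or binary format.
    binary : bool, optional
        Force the dialect; by default it is sniffed (a well-formed UTF-8
        text body is assumed text, otherwise binary).

    Raises
    ------
    ValueError
        On a malformed header, a row whose dimension does not match the
        header, a duplicate word, or a row-count mismatch.
    """
    path = Path(path)
    raw = path.read_bytes()
    if binary is None:
        binary = _sniff_binary(raw)
    return _load_binary(raw, path) if binary else _load_text(raw, path)


def _sniff_binary(raw: bytes) -> bool:
    try:
        raw.decode("utf-8")
    except UnicodeDecodeError:
        return True
    return False


def _parse_header(line: bytes, path: Path) -> tuple[int, int]:
    parts = line.split()
    if len(parts) != 2:
        raise ValueError(f"{path}: malformed word2vec header {line!r}")
    try:
        n, dim = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed word2vec header {line!r}") from exc
    if n < 0 or dim <= 0:
        raise ValueError(f"{path}: malformed word2vec header {line!r}")
    return n, dim


def _load_text(raw: bytes, path: Path) -> dict[str, np.ndarray]:
    lines = raw.decode("utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty vector file")
    n, dim = _parse_header(lines[0].encode(), path)
    body = [ln for ln in lines[1:] if ln.strip()]
    if len(body) != n:
        raise ValueError(f"{path}: header declares {n} rows, found {len(body)}")
    vectors: dict[str, np.ndarray] = {}
    for ln in body:
        parts = ln.rstrip().split(" ")
        word = parts[0]
        if word in vectors:
            raise ValueError(f"{path}: duplicate word {word!r}")
        vec = np.array(parts[1:], dtype=np.float32)
        if vec.shape != (dim,):
            raise ValueError(
                f"{path}: word {word!r} has {vec.size} values, expected {dim}"
            )
        vectors[word] = vec
    return vectors


def _load_binary(raw: bytes, path: Path) -> dict[str, np.ndarray]:
    nl = raw.index(b"\n")
    n, dim = _parse_header(raw[:nl], path)
    pos = nl + 1
    row_bytes = 4 * dim
    vectors: dict[str, np.ndarray] = {}
    for _ in range(n):
        sp = raw.index(b" ", pos)
        word = raw[pos:sp].lstrip(b"\n").decode("utf-8")
        if word in vectors:
            raise ValueError(f"{path}: duplicate word {word!r}")
        start = sp + 1
        end = start + row_bytes
        if end > len(raw):
            raise ValueError(f"{path}: truncated binary row for {word!r}")
        vectors[word] = np.frombuffer(raw[start:end], dtype="<f4").copy()
        pos = end
    if raw[pos:].strip():
        raise ValueError(f"{path}: trailing data after {n} declared rows")
    return vectors


def save_word2vec(
    vectors: Mapping[str, np.ndarray] | "WordVectors",
    path: str | Path,
    binary: bool = False,
) -> None:
    """Write word vectors in word2vec text or binary format."""
    if isinstance(vectors, WordVectors):
        vectors = dict(zip(vectors.words, vectors.matrix))
    path = Path(path)
    words = list(vectors)
    if not words:
        raise ValueError("no vectors to save")
    dim = len(np.asarray(vectors[words[0]]))
    if binary:
        with open(path, "wb") as fh:
            fh.write(f"{len(words)} {dim}\n".encode())
            for w in words:
                vec = np.asarray(vectors[w], dtype="<f4")
                fh.write(w.encode("utf-8") + b" " + vec.tobytes() + b"\n")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(words)} {dim}\n")
            for w in words:
                row = " ".join(f"{x:.7g}" for x in np.asarray(vectors[w]))
                fh.write(f"{w} {row}\n")


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity ``a.b / (|a||b|)``; zero vectors are rejected."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine undefined for zero vector")
    return float(np.dot(a, b) / (na * nb))


def normalize_rows(matrix: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Return a copy of ``matrix`` with unit-norm rows (zero rows stay zero)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    return matrix / np.maximum(norms, eps)


class WordVectors:
    """An ordered (words, matrix) pair with cosine queries.

    A light in-memory container used for trained embeddings, pre-trained
    sources restricted to a vocabulary, and reference models during tuning.
    """

    def __init__(self, words: Sequence[str], matrix: np.ndarray):
        self.words = list(words)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.words):
            raise ValueError("matrix shape does not match word list")
        self.index = {w: i for i, w in enumerate(self.words)}
        if len(self.index) != len(self.words):
            raise ValueError("duplicate words")

    @classmethod
    def from_mapping(cls, vectors: Mapping[str, np.ndarray]) -> "WordVectors":
        words = list(vectors)
        return cls(words, np.array([vectors[w] for w in words]))

    @classmethod
    def load(cls, path: str | Path, binary: bool | None = None) -> "WordVectors":
        return cls.from_mapping(load_word2vec(path, binary=binary))

    def save(self, path: str | Path, binary: bool = False) -> None:
        save_word2vec(self, path, binary=binary)

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def __getitem__(self, word: str) -> np.ndarray:
        return self.matrix[self.index[word]]

    def restrict(self, words: Sequence[str]) -> "WordVectors":
        """Subset to ``words`` (kept in the given order); unknown words error."""
        rows = [self.index[w] for w in words]
        return WordVectors(list(words), self.matrix[rows])

    def shared_words(self, other: "WordVectors") -> list[str]:
        return [w for w in self.words if w in other.index]

    def unit(self) -> np.ndarray:
        return normalize_rows(self.matrix)
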