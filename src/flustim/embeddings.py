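"""Word-vector storage and the cosine-similarity primitive.

All switching computations operate on pretrained word vectors in the
word2vec *text* format (header line ``<vocab_count> <dimension>`` followed by
one ``word v1 ... vD`` row per word).  The store is vector-source agnostic:
any embedding exported to that format (fastText, word2vec, GloVe converted)
can be used.  Vectors are kept exactly as read — cosine similarity is
scale-invariant, and not normalising preserves round-trip fidelity.
"""
from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "EmbeddingParseError",
    "EmbeddingStore",
    "load_embeddings",
    "write_embeddings",
    "cosine_similarity",
    "resolve_token",
]


class _MissingType:
    """Sentinel for an out-of-vocabulary token under the ``skip`` policy."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _MissingType()


class EmbeddingParseError(ValueError):
    """Raised when an embedding file violates the word2vec text format."""


class EmbeddingStore:
    """Immutable vocabulary -> vector mapping of fixed dimension.

    Parameters
    ----------
    vectors
        Mapping from word to a 1-D float array.  Every vector must have the
        same length and nonzero norm.
    """

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding store must contain at least one word")
        dim = None
        store: dict[str, np.ndarray] = {}
        for word, vec in vectors.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"vector for {word!r} is not 1-D")
            if dim is None:
                dim = arr.size
            elif arr.size != dim:
                raise ValueError(
                    f"vector for {word!r} has length {arr.size}, expected {dim}"
                )
            if not np.any(arr):
                raise ValueError(f"vector for {word!r} has zero norm")
            arr.flags.writeable = False
            store[word] = arr
        self._vectors = store
        self._dimension = int(dim)

    @property
    def dimension(self) -> int:
        return self._dimension

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self._vectors)

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self._vectors[word]

    def get(self, word: str, default=None):
        return self._vectors.get(word, default)

    def items(self):
        return self._vectors.items()


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def load_embeddings(path: Union[str, Path]) -> EmbeddingStore:
    """Parse a word2vec-text file (optionally gzipped) into a store.

    Raises :class:`EmbeddingParseError` naming the offending line for a
    malformed header, a row whose width disagrees with the header dimension,
    a duplicate word, a zero-norm vector, or a row count that disagrees with
    the header vocabulary count.
    """
    vectors: dict[str, np.ndarray] = {}
    with _open_text(path) as handle:
        header = handle.readline()
        parts = header.split()
        if len(parts) != 2:
            raise EmbeddingParseError(f"line 1: malformed header {header.strip()!r}")
        try:
            n_words, dim = int(parts[0]), int(parts[1])
        except ValueError:
            raise EmbeddingParseError(
                f"line 1: header fields must be integers, got {header.strip()!r}"
            ) from None
        if n_words <= 0 or dim <= 0:
            raise EmbeddingParseError(f"line 1: nonpositive header counts {header.strip()!r}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split()
            word = fields[0]
            if len(fields) - 1 != dim:
                raise EmbeddingParseError(
                    f"line {lineno}: expected {dim} components for {word!r}, "
                    f"got {len(fields) - 1}"
                )
            if word in vectors:
                raise EmbeddingParseError(f"line {lineno}: duplicate word {word!r}")
            try:
                vec = np.array([float(x) for x in fields[1:]], dtype=float)
            except ValueError:
                raise EmbeddingParseError(
                    f"line {lineno}: non-numeric component for {word!r}"
                ) from None
            if not np.any(vec):
                raise EmbeddingParseError(f"line {lineno}: zero-norm vector for {word!r}")
            vectors[word] = vec
    if len(vectors) != n_words:
        raise EmbeddingParseError(
            f"header declares {n_words} words but file contains {len(vectors)}"
        )
    return EmbeddingStore(vectors)


def write_embeddings(store: EmbeddingStore, path: Union[str, Path]) -> None:
    """Write a store back to word2vec text format (repr-round-trip floats)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="utf-8") as handle:
        handle.write(f"{len(store)} {store.dimension}\n")
        for word, vec in store.items():
            handle.write(word + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def cosine_similarity(u: Iterable[float], v: Iterable[float]) -> float:
    """cos(u, v) = u.v / (|u| |v|), clipped to [-1, 1].

    Symmetric and invariant to positive rescaling of either argument.
    Zero-norm or length-mismatched inputs raise ``ValueError``.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    if np.array_equal(u, v):
        return 1.0  # exact, so the strict threshold rule treats repeats as same-cluster
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def resolve_token(token: str, store: EmbeddingStore, policy: str = "skip"):
    """Map a response token to a vector.

    Single in-vocabulary words return their stored vector.  Multiword tokens
    (whitespace-split) return the unweighted componentwise mean of the
    constituents that are in vocabulary.  A fully out-of-vocabulary token
    returns :data:`MISSING` under ``policy="skip"`` (with a logged warning)
    or raises ``KeyError`` under ``policy="error"``.
    """
    if policy not in ("skip", "error"):
        raise ValueError(f"unknown oov policy {policy!r}")
    token = token.strip()
    if not token:
        return _oov(token, policy)
    if token in store:
        return store[token]
    parts = token.split()
    if len(parts) > 1:
        found = [store[p] for p in parts if p in store]
        if found:
            return np.mean(found, axis=0)
    lowered = token.lower()
    if lowered in store:
        return store[lowered]
    return _oov(token, policy)


def _oov(token: str, policy: str):
    if policy == "error":
        raise KeyError(f"token {token!r} is not resolvable in the embedding store")
    logger.warning("out-of-vocabulary token skipped: %r", token)
    return MISSING
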