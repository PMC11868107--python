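"""Word-embedding store and target–response cosine similarity.

Semantic relatedness between a target and a real-word response is scored as
the cosine of their word-embedding vectors, as produced by a word2vec-style
model.  Training models is out of scope: only loading (word2vec text and
binary formats) and the cosine computation live here.  Out-of-vocabulary
or missing words yield a missing value, never an error — downstream
classification treats a missing cosine as "not semantically related" and
records an audit note.
"""

from __future__ import annotations

import struct
import unicodedata
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

__all__ = ["EmbeddingStore", "load_embeddings", "get_semantic_similarity"]


def _norm(word: str) -> str:
    return unicodedata.normalize("NFC", word.strip().casefold())


class EmbeddingStore:
    """In-memory word → vector mapping with a fixed dimension.

    Lookups are case-folded and NFC-normalized; there is no subword
    fallback.
    """

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise FormatError("embedding store has an empty vocabulary")
        normed = {_norm(w): np.asarray(v, dtype=float) for w, v in vectors.items()}
        dims = {v.shape for v in normed.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise FormatError(f"inconsistent vector shapes: {sorted(dims)}")
        self._vectors = normed
        self.dimension = next(iter(dims))[0]

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, word: str) -> bool:
        return _norm(word) in self._vectors

    @property
    def vocabulary(self) -> list[str]:
        return sorted(self._vectors)

    def get(self, word: str) -> np.ndarray | None:
        return self._vectors.get(_norm(word))

    def cosine(self, word_a: str, word_b: str) -> float:
        """Cosine similarity of two words' vectors; NaN when either word is
        blank, out of vocabulary, or has a zero vector."""
        if not word_a or not str(word_a).strip() or not word_b or not str(word_b).strip():
            return float("nan")
        u = self.get(str(word_a))
        v = self.get(str(word_b))
        if u is None or v is None:
            return float("nan")
        nu = float(np.linalg.norm(u))
        nv = float(np.linalg.norm(v))
        if nu == 0.0 or nv == 0.0:
            return float("nan")
        return float(np.dot(u, v) / (nu * nv))

    def save_word2vec_text(self, path: str | Path, fmt: str = "%.8g") -> None:
        """Write the store in word2vec text format (header + one row per word)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self._vectors)} {self.dimension}\n")
            for word in sorted(self._vectors):
                values = " ".join(fmt % x for x in self._vectors[word])
                fh.write(f"{word} {values}\n")


def _load_text(path: Path, normalize: bool) -> EmbeddingStore:
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split()
        if len(header) != 2:
            raise FormatError(f"{path}:1: expected header 'vocab_size dimension'")
        try:
            vocab_size, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise FormatError(f"{path}:1: non-integer header fields {header}") from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            word, values = parts[0], parts[1:]
            if len(values) != dim:
                raise FormatError(
                    f"{path}:{lineno}: expected {dim} values for {word!r}, got {len(values)}"
                )
            try:
                vec = np.array([float(x) for x in values])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
            vectors[word] = vec
    if len(vectors) != vocab_size:
        raise FormatError(
            f"{path}: header declares {vocab_size} words, file holds {len(vectors)}"
        )
    return _finish(vectors, normalize)


def _load_binary(path: Path, normalize: bool) -> EmbeddingStore:
    vectors: dict[str, np.ndarray] = {}
    with open(path, "rb") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: expected binary header 'vocab_size dimension'")
        vocab_size, dim = int(header[0]), int(header[1])
        row_bytes = 4 * dim
        for _ in range(vocab_size):
            word_bytes = bytearray()
            while True:
                ch = fh.read(1)
                if not ch:
                    raise FormatError(f"{path}: truncated binary file")
                if ch == b" ":
                    break
                if ch != b"\n":
                    word_bytes.extend(ch)
            raw = fh.read(row_bytes)
            if len(raw) != row_bytes:
                raise FormatError(f"{path}: truncated vector data")
            vec = np.array(struct.unpack(f"<{dim}f", raw), dtype=float)
            vectors[word_bytes.decode("utf-8")] = vec
    return _finish(vectors, normalize)


def _finish(vectors: dict[str, np.ndarray], normalize: bool) -> EmbeddingStore:
    if normalize:
        for word, vec in vectors.items():
            norm = np.linalg.norm(vec)
            if norm > 0:
                vectors[word] = vec / norm
    return EmbeddingStore(vectors)


def load_embeddings(
    path: str | Path,
    format: str = "word2vec-text",
    normalize: bool = False,
) -> EmbeddingStore:
    """Load a word-embedding table.

    ``format`` is ``"word2vec-text"`` (header line ``vocab_size dimension``
    followed by ``word v1 … vD`` rows) or ``"word2vec-binary"`` (same
    header, little-endian float32 rows).  With ``normalize`` the vectors
    are scaled to unit length on load (cosines are unaffected).
    """
    path = Path(path)
    if format == "word2vec-text":
        return _load_text(path, normalize)
    if format == "word2vec-binary":
        return _load_binary(path, normalize)
    raise FormatError(f"unknown embedding format {format!r}")


def get_semantic_similarity(
    records: pd.DataFrame,
    item_col: str = "item",
    response_col: str = "response",
    store: EmbeddingStore | None = None,
) -> pd.DataFrame:
    """Add a ``w2v_cos`` column with the target–response cosine similarity.

    Missing, blank or out-of-vocabulary words yield NaN (missingness is a
    value, not an error).
    """
    if store is None:
        raise ConfigurationError(
            "get_semantic_similarity requires a loaded EmbeddingStore"
        )
    for col, name in ((item_col, "item_col"), (response_col, "response_col")):
        if col not in records.columns:
            raise ConfigurationError(f"{name} {col!r} not found in table")
    out = records.copy()
    items = out[item_col].fillna("").astype(str)
    responses = out[response_col].fillna("").astype(str)
    out["w2v_cos"] = [store.cosine(i, r) for i, r in zip(items, responses)]
    return out
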