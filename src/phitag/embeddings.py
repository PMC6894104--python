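"""Pretrained word-vector loading and lookup.

Reads the plain-text formats written by word2vec and fastText (optional
``count dim`` header, then one ``word v1 ... vd`` row per line).  Tokens
absent from the vocabulary fall back first to their case-folded form and
finally to a dedicated UNKNOWN vector, mirroring how out-of-vocabulary
words are replaced at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import ParseError

logger = logging.getLogger(__name__)

UNKNOWN = "UNKNOWN"

#: Seed used to sample the UNKNOWN row when the vector file lacks one.
UNKNOWN_SEED = 201901


@dataclass
class EmbeddingMatrix:
    """Vocabulary plus a dense (n_words, dim) vector matrix."""

    vocab: dict[str, int]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        if UNKNOWN not in self.vocab:
            raise ValueError("EmbeddingMatrix requires an UNKNOWN row")

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    @property
    def unknown_vector(self) -> np.ndarray:
        return self.vectors[self.vocab[UNKNOWN]]


def load_vectors(path: str | Path,
                 fmt: str = "word2vec_text") -> EmbeddingMatrix:
    """Load a plain-text vector file into an :class:`EmbeddingMatrix`.

    Duplicate words keep their first occurrence (with a warning); ragged
    rows raise :class:`ParseError` with the offending line number.  If the
    file has no UNKNOWN row, one is drawn uniform in [-0.25, 0.25] from a
    fixed seed so repeated loads are identical.
    """
    if fmt not in ("word2vec_text", "fastText_text"):
        raise ValueError(f"unknown vector format {fmt!r}")
    path = Path(path)
    vocab: dict[str, int] = {}
    rows: list[np.ndarray] = []
    dim: int | None = None
    declared_count: int | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            parts = [p for p in parts if p]
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    declared_count, dim = int(parts[0]), int(parts[1])
                    continue
                except ValueError:
                    pass  # not a header; fall through as a data row
            word, values = parts[0], parts[1:]
            try:
                vec = np.asarray([float(v) for v in values], dtype=np.float64)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric vector component") from None
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ParseError(
                    f"{path}:{lineno}: expected {dim} components, "
                    f"got {vec.size}")
            if word in vocab:
                logger.warning("%s:%d: duplicate word %r (first kept)",
                               path, lineno, word)
                continue
            vocab[word] = len(rows)
            rows.append(vec)
    if dim is None:
        raise ParseError(f"{path}: no vector rows")
    if declared_count is not None and declared_count != len(rows):
        raise ParseError(
            f"{path}: header declares {declared_count} rows, "
            f"file contains {len(rows)}")
    if UNKNOWN not in vocab:
        rng = np.random.default_rng(UNKNOWN_SEED)
        vocab[UNKNOWN] = len(rows)
        rows.append(rng.uniform(-0.25, 0.25, size=dim))
    return EmbeddingMatrix(vocab, np.vstack(rows))


def lookup(word: str, m: EmbeddingMatrix) -> np.ndarray:
    """Vector for *word*: exact form, then case-folded, then UNKNOWN."""
    idx = m.vocab.get(word)
    if idx is None:
        idx = m.vocab.get(word.lower())
    if idx is None:
        idx = m.vocab[UNKNOWN]
    return m.vectors[idx]
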