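"""Word-embedding model: loading, cosine similarity, phrase vectors, k-NN.

The on-disk format is the word2vec *text* format (a ``"<vocab> <dim>"``
header, then one ``"<token> <dim floats>"`` line per entry). Vocabulary
keys are NFC-normalized and lowercased; out-of-vocabulary lookups are
reported as OOV (``None``), never imputed — an imputed vector would
silently distort every context-similarity average downstream.

Phrase vectors are the arithmetic mean of the vectors of the phrase's
content words (nouns, lexical verbs, adjectives, adverbs); function words
and OOV tokens are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._text import normalize

logger = logging.getLogger(__name__)

#: Closed coarse tagset used throughout the package.
COARSE_TAGS = frozenset({"NN", "ADJ", "PREP", "VB", "ADV", "DET", "OTHER"})

#: Tags that count as content words for phrase averaging.
CONTENT_TAGS = frozenset({"NN", "VB", "ADJ", "ADV"})


class EmbeddingLoadError(ValueError):
    """Malformed word2vec text input; the message names the offending line."""


@dataclass(frozen=True)
class TaggedToken:
    """A surface token with a coarse POS tag and codepoint offsets."""

    surface: str
    tag: str
    char_start: int = 0
    char_end: int = -1

    def __post_init__(self) -> None:
        if self.tag not in COARSE_TAGS:
            raise ValueError(f"unknown coarse tag {self.tag!r}")
        if self.char_end < 0:
            object.__setattr__(self, "char_end", self.char_start + len(self.surface))
        if not self.char_start < self.char_end:
            raise ValueError("char_start must be < char_end")

    @property
    def key(self) -> str:
        return normalize(self.surface)


class EmbeddingModel:
    """Vocabulary-to-vector mapping with a fixed dimension.

    Parameters
    ----------
    dimension
        Length of every stored vector.
    entries
        Mapping from surface form to vector. Keys are normalized (NFC,
        lowercased) on construction; duplicate keys after normalization
        keep the first occurrence.
    """

    def __init__(self, dimension: int, entries: dict[str, np.ndarray]):
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        self.dimension = int(dimension)
        self._entries: dict[str, np.ndarray] = {}
        for key, vec in entries.items():
            nkey = normalize(key)
            if not nkey:
                raise ValueError("zero-length vocabulary entry")
            vec = np.asarray(vec, dtype=np.float64)
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"entry {key!r} has length {vec.size}, expected {self.dimension}"
                )
            if nkey in self._entries:
                logger.warning("duplicate vocabulary key %r after normalization", nkey)
                continue
            self._entries[nkey] = vec
        if self._entries and not any(
            np.linalg.norm(v) > 0 for v in self._entries.values()
        ):
            raise ValueError("all stored vectors have zero norm")
        self._keys: list[str] | None = None
        self._matrix: np.ndarray | None = None
        self._norms: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, surface: str) -> bool:
        return normalize(surface) in self._entries

    def __getitem__(self, surface: str) -> np.ndarray:
        return self._entries[normalize(surface)]

    def get(self, surface: str) -> np.ndarray | None:
        """Vector for ``surface``, or ``None`` when out of vocabulary."""
        return self._entries.get(normalize(surface))

    def vocabulary(self) -> list[str]:
        return sorted(self._entries)

    def _dense(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        if self._matrix is None:
            self._keys = sorted(self._entries)
            self._matrix = np.stack([self._entries[k] for k in self._keys])
            self._norms = np.linalg.norm(self._matrix, axis=1)
        return self._keys, self._matrix, self._norms  # type: ignore[return-value]


def load_embeddings(path, expected_dimension: int | None = None) -> EmbeddingModel:
    """Load a word2vec text-format file.

    Raises :class:`EmbeddingLoadError` naming the line number on a malformed
    header, a vector-length mismatch, or a dimension differing from
    ``expected_dimension``.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        parts = header.split()
        if len(parts) != 2:
            raise EmbeddingLoadError(f"line 1: malformed header {header.strip()!r}")
        try:
            vocab_size, dimension = int(parts[0]), int(parts[1])
        except ValueError:
            raise EmbeddingLoadError(
                f"line 1: non-integer header fields {header.strip()!r}"
            ) from None
        if vocab_size < 0 or dimension <= 0:
            raise EmbeddingLoadError(f"line 1: invalid header counts {header.strip()!r}")
        if expected_dimension is not None and dimension != expected_dimension:
            raise EmbeddingLoadError(
                f"line 1: dimension {dimension} != expected {expected_dimension}"
            )
        entries: dict[str, np.ndarray] = {}
        for lineno in range(2, vocab_size + 2):
            line = fh.readline()
            if not line:
                raise EmbeddingLoadError(
                    f"line {lineno}: file ends before {vocab_size} entries were read"
                )
            fields = line.rstrip("\n").split(" ")
            fields = [f for f in fields if f != ""]
            token, floats = fields[0], fields[1:]
            if len(floats) != dimension:
                raise EmbeddingLoadError(
                    f"line {lineno}: expected {dimension} floats, got {len(floats)}"
                )
            try:
                vec = np.array([float(x) for x in floats], dtype=np.float64)
            except ValueError:
                raise EmbeddingLoadError(
                    f"line {lineno}: non-numeric vector component"
                ) from None
            nkey = normalize(token)
            if not nkey:
                raise EmbeddingLoadError(f"line {lineno}: empty token")
            if nkey in entries:
                logger.warning(
                    "line %d: duplicate key %r after normalization; keeping first",
                    lineno,
                    nkey,
                )
                continue
            entries[nkey] = vec
    return EmbeddingModel(dimension, entries)


def save_embeddings(model: EmbeddingModel, path) -> None:
    """Write a model back out in word2vec text format (sorted vocabulary)."""
    keys = model.vocabulary()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(keys)} {model.dimension}\n")
        for key in keys:
            vec = " ".join(repr(float(x)) for x in model[key])
            fh.write(f"{key} {vec}\n")


def cosine(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine of the angle between two vectors.

    A zero vector on either side yields 0.0 with a warning: a degenerate
    entry is "similar to nothing" rather than an error, so one bad vector
    cannot abort a batch run.
    """
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape:
        raise ValueError("cosine requires vectors of equal length")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        logger.warning("cosine of a zero vector defined as 0.0")
        return 0.0
    return float(np.dot(v1, v2) / (n1 * n2))


def phrase_vector(model: EmbeddingModel, tokens) -> np.ndarray | None:
    """Mean of the vectors of in-vocabulary content-word tokens.

    Tokens whose tag is not in :data:`CONTENT_TAGS` and OOV tokens are
    skipped; the result is OOV (``None``) iff no token contributes.
    """
    if not tokens:
        raise ValueError("phrase_vector requires at least one token")
    contributing = []
    for tok in tokens:
        if tok.tag not in CONTENT_TAGS:
            continue
        vec = model.get(tok.surface)
        if vec is None:
            logger.debug("phrase token %r is OOV; skipped", tok.surface)
            continue
        contributing.append(vec)
    if not contributing:
        return None
    return np.mean(np.stack(contributing), axis=0)


def nearest_neighbors(
    model: EmbeddingModel,
    query: np.ndarray,
    k: int = 10,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[tuple[str, float]]:
    """Top-``k`` vocabulary entries by cosine to ``query``.

    Descending cosine order, ties broken lexicographically; excluded
    surface forms (normalized) never appear. Fewer than ``k`` results are
    returned when the vocabulary is small. A zero query yields an empty
    list with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    query = np.asarray(query, dtype=np.float64)
    qnorm = np.linalg.norm(query)
    if qnorm == 0.0:
        logger.warning("nearest_neighbors on a zero query vector; returning []")
        return []
    excluded = {normalize(s) for s in exclude}
    keys, matrix, norms = model._dense()
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = matrix @ query / (norms * qnorm)
    sims = np.where(norms == 0.0, 0.0, sims)
    scored = [
        (key, float(sim)) for key, sim in zip(keys, sims) if key not in excluded
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored[:k]
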