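"""Harvesting multi-word adverse-effect phrase candidates.

Noun phrases are detected in a POS-tagged corpus by matching a small set of
NN-headed tag patterns; a phrase is kept only if (a) at least one of its
tokens belongs to the anchor lexicon (emulating the MedDRA-membership
constraint that keeps the harvest from drowning in generic noun phrases)
and (b) its content words yield a non-OOV phrase embedding. Kept phrases
are stored with their precomputed phrase vectors.

The harvester consumes pre-tagged input (``token<TAB>tag`` TSV, blank line
= sentence break) plus an optional mapping from the tagger's tagset to the
coarse tagset {NN, ADJ, PREP, VB, ADV, DET, OTHER}; this decouples the
method from any particular POS tagger.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from ._text import normalize
from .embeddings import COARSE_TAGS, EmbeddingModel, TaggedToken, phrase_vector
from .gazetteer import Lexicon

logger = logging.getLogger(__name__)

_PATTERN_TAGS = frozenset({"NN", "ADJ", "PREP", "VB", "ADV", "DET"})


@dataclass(frozen=True)
class POSPattern:
    """A coarse-tag sequence; every pattern is NN-headed."""

    tag_sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tag_sequence:
            raise ValueError("empty pattern")
        if self.tag_sequence[0] != "NN":
            raise ValueError("patterns must be NN-headed")
        bad = set(self.tag_sequence) - _PATTERN_TAGS
        if bad:
            raise ValueError(f"unknown pattern tags: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.tag_sequence)


def default_patterns() -> list[POSPattern]:
    """The four stock noun-phrase patterns, in fixed precedence order.

    NN ADJ ("sueño anormal"), NN PREP NN ("enfermedad del estómago"),
    NN PREP VB ("problemas para tragar"), NN ADJ PREP NN
    ("azucar alta en sangre").
    """
    return [
        POSPattern(("NN", "ADJ")),
        POSPattern(("NN", "PREP", "NN")),
        POSPattern(("NN", "PREP", "VB")),
        POSPattern(("NN", "ADJ", "PREP", "NN")),
    ]


def _match_at(tokens, i, pattern: POSPattern, allow_det_after_prep: bool) -> int | None:
    """Length (in tokens) of a match of ``pattern`` at position ``i``, else None.

    When ``allow_det_after_prep`` is on, a single DET token may intervene
    between a PREP and the tag the pattern expects next ("trastornos de la
    alimentación" matching NN PREP NN).
    """
    j = i
    n = len(tokens)
    prev: str | None = None
    for ptag in pattern.tag_sequence:
        if allow_det_after_prep and prev == "PREP" and j < n and tokens[j].tag == "DET":
            j += 1
        if j >= n or tokens[j].tag != ptag:
            return None
        j += 1
        prev = ptag
    return j - i


def match_patterns(
    tokens,
    patterns=None,
    allow_det_after_prep: bool = True,
) -> list[tuple[int, int]]:
    """Maximal non-overlapping pattern matches, scanning left to right.

    Returns ``(start, end)`` token-index spans. When several patterns match
    at one position the longest span wins; ties go to pattern order.
    """
    if patterns is None:
        patterns = default_patterns()
    spans: list[tuple[int, int]] = []
    i = 0
    n = len(tokens)
    while i < n:
        best_len = 0
        for pattern in patterns:  # earlier pattern wins ties (strict >)
            length = _match_at(tokens, i, pattern, allow_det_after_prep)
            if length is not None and length > best_len:
                best_len = length
        if best_len:
            spans.append((i, i + best_len))
            i += best_len
        else:
            i += 1
    return spans


@dataclass
class PhraseEntry:
    text: str
    tokens: list[TaggedToken]
    vector: np.ndarray

    @property
    def tags(self) -> list[str]:
        return [t.tag for t in self.tokens]


@dataclass
class PhraseStore:
    """Harvested phrases with vectors, plus kept/rejected accounting."""

    phrases: dict[str, PhraseEntry] = field(default_factory=dict)
    rejected: dict[str, int] = field(default_factory=dict)

    @property
    def kept(self) -> int:
        return len(self.phrases)

    @property
    def total_spans(self) -> int:
        return self.kept + sum(self.rejected.values())

    def __len__(self) -> int:
        return len(self.phrases)

    def __contains__(self, phrase: str) -> bool:
        return normalize(phrase) in self.phrases

    def items(self):
        return sorted(self.phrases.items())

    def save(self, path) -> None:
        """One JSON object per line: {phrase, tags, vector}."""
        with open(path, "w", encoding="utf-8") as fh:
            for text, entry in self.items():
                fh.write(
                    json.dumps(
                        {
                            "phrase": text,
                            "tags": entry.tags,
                            "vector": [float(x) for x in entry.vector],
                        },
                        ensure_ascii=False,
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, path) -> "PhraseStore":
        store = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                surfaces = obj["phrase"].split()
                tokens = [
                    TaggedToken(surface=s, tag=t)
                    for s, t in zip(surfaces, obj["tags"])
                ]
                store.phrases[obj["phrase"]] = PhraseEntry(
                    text=obj["phrase"],
                    tokens=tokens,
                    vector=np.array(obj["vector"], dtype=np.float64),
                )
        return store


def read_tagged_corpus(path, tagmap: dict[str, str] | None = None):
    """Yield sentences (lists of :class:`TaggedToken`) from token/tag TSV.

    Blank lines separate sentences. Tags are mapped through ``tagmap`` when
    given; tags outside the coarse tagset map to OTHER. Unreadable lines
    are skipped with a warning, never aborting the stream.
    """
    sentence: list[TaggedToken] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if sentence:
                    yield sentence
                    sentence = []
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip():
                logger.warning("skipping unreadable corpus line %d: %r", lineno, line)
                continue
            surface, tag = parts[0].strip(), parts[1].strip()
            if tagmap is not None:
                tag = tagmap.get(tag, tag)
            if tag not in COARSE_TAGS:
                tag = "OTHER"
            sentence.append(TaggedToken(surface=surface, tag=tag))
    if sentence:
        yield sentence


def load_tagmap(path) -> dict[str, str]:
    """Two-column TSV mapping a tagger's tags to the coarse tagset."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            src, dst = line.split("\t", 1)
            mapping[src.strip()] = dst.strip()
    return mapping


def harvest(
    corpus,
    anchor: Lexicon,
    model: EmbeddingModel,
    patterns=None,
    allow_det_after_prep: bool = True,
) -> PhraseStore:
    """Collect anchored, in-vocabulary noun phrases from a tagged corpus.

    ``corpus`` is an iterable of tagged sentences (see
    :func:`read_tagged_corpus`). Each matched span is kept iff at least one
    of its tokens is an anchor-lexicon word and its phrase vector is
    non-OOV; duplicates (after normalization) are stored once. The store
    records counts of rejected spans by reason ("no-anchor", "oov",
    "duplicate"), so kept + rejected equals the total number of matches.
    """
    if patterns is None:
        patterns = default_patterns()
    store = PhraseStore()
    for sentence in corpus:
        for start, end in match_patterns(sentence, patterns, allow_det_after_prep):
            span = sentence[start:end]
            text = " ".join(normalize(tok.surface) for tok in span)
            if not any(anchor.contains_word(tok.surface) for tok in span):
                store.rejected["no-anchor"] = store.rejected.get("no-anchor", 0) + 1
                continue
            vector = phrase_vector(model, span)
            if vector is None:
                store.rejected["oov"] = store.rejected.get("oov", 0) + 1
                continue
            if text in store.phrases:
                store.rejected["duplicate"] = store.rejected.get("duplicate", 0) + 1
                continue
            store.phrases[text] = PhraseEntry(
                text=text,
                tokens=[TaggedToken(surface=t.key, tag=t.tag) for t in span],
                vector=vector,
            )
    logger.info(
        "harvest: kept %d phrases, rejected %s", store.kept, dict(store.rejected)
    )
    return store
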