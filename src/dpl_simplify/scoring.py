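"""Candidate scoring: context similarity, informativeness, the final rank.

Two quantities drive substitution. *Context similarity* is the mean cosine
between a candidate's vector and the vectors of the words surrounding the
target mention (a window of three tokens on each side, clipped at sentence
boundaries); it guards against picking a synonym of the wrong sense of a
polysemous word. *Informativeness* ci(w) = −log((freq(w)+1) / (N+1)),
with N the total count mass of a background frequency table, scores how
rare — and hence presumably how complex — a word is: rarer words carry
more information. A candidate may replace the original term only if it is
strictly *less* informative (more frequent, simpler).

The final ranking score is the convex combination
``alpha * sim_target + (1 - alpha) * csim`` (default alpha = 0.5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._text import guess_tag, iter_sentences, normalize, tokenize
from .embeddings import CONTENT_TAGS, EmbeddingModel, TaggedToken, cosine
from .gazetteer import EffectMention

logger = logging.getLogger(__name__)


class FrequencyTable:
    """Word → count mapping with a cached total, read from word/count TSV.

    Absent words have count 0; the +1 smoothing in the informativeness
    formula keeps them finite.
    """

    def __init__(self, counts: dict[str, int]):
        self.counts: dict[str, int] = {}
        for word, count in counts.items():
            if count < 0:
                raise ValueError(f"negative count for {word!r}")
            self.counts[normalize(word)] = int(count)
        self.total = sum(self.counts.values())

    def freq(self, word: str) -> int:
        return self.counts.get(normalize(word), 0)

    def __len__(self) -> int:
        return len(self.counts)

    @classmethod
    def load(cls, path) -> "FrequencyTable":
        """TSV ``word<TAB>count``; '#' comments and blank lines skipped."""
        counts: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    word, count = line.split("\t")
                    counts[normalize(word)] = (
                        counts.get(normalize(word), 0) + int(count)
                    )
                except ValueError:
                    raise ValueError(
                        f"{path}: malformed frequency line {lineno}: {line!r}"
                    ) from None
        return cls(counts)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for word in sorted(self.counts):
                fh.write(f"{word}\t{self.counts[word]}\n")


@dataclass
class Candidate:
    """A proposed substitute with its similarity and complexity scores."""

    text: str
    vector: np.ndarray
    sim_target: float = 0.0
    csim: float = 0.0
    informativeness: float = 0.0
    final_score: float = 0.0
    is_phrase: bool = False


@dataclass
class ContextWindow:
    """In-vocabulary tokens around a mention, the mention itself excluded."""

    target: EffectMention
    context_words: list[str] = field(default_factory=list)


def build_context_window(
    text: str,
    mention: EffectMention,
    model: EmbeddingModel,
    window_size: int = 3,
) -> ContextWindow:
    """Up to ``window_size`` tokens each side of the mention, within its
    sentence, restricted to in-vocabulary words (OOV tokens are skipped)."""
    spans = list(iter_sentences(text))
    s_start, s_end = (
        spans[mention.sentence_index]
        if 0 <= mention.sentence_index < len(spans)
        else (0, len(text))
    )
    words: list[str] = []
    before: list[str] = []
    after: list[str] = []
    for surface, start, end in tokenize(text[s_start:s_end]):
        abs_start = start + s_start
        abs_end = end + s_start
        if abs_end <= mention.char_start:
            before.append(surface)
        elif abs_start >= mention.char_end:
            after.append(surface)
        # tokens inside the mention span are the target itself: excluded
    window = before[-window_size:] + after[:window_size]
    words = [w for w in window if model.get(w) is not None]
    return ContextWindow(target=mention, context_words=words)


def context_similarity(
    candidate_vector: np.ndarray,
    window: ContextWindow,
    model: EmbeddingModel,
) -> float:
    """Mean cosine between the candidate and each context-word vector.

    An empty context yields 0.0 (logged): with nothing to compare against,
    the candidate is neither supported nor penalized by context.
    """
    if not window.context_words:
        logger.debug("empty context window for %r", window.target.surface)
        return 0.0
    sims = [
        cosine(candidate_vector, model[w]) for w in window.context_words
    ]
    return float(sum(sims) / len(sims))


def informativeness(word: str, table: FrequencyTable) -> float:
    """ci(w) = −log((freq(w)+1) / (N+1)), natural log.

    Non-negative under this reading, zero only for a word carrying the
    entire count mass, and strictly decreasing in freq(w). Words absent
    from the table use freq 0.
    """
    if table.total <= 0:
        raise ValueError("frequency table has no mass")
    return -math.log((table.freq(word) + 1) / (table.total + 1))


def phrase_informativeness(phrase_tokens, table: FrequencyTable) -> float:
    """Mean informativeness over a phrase's content words (NN/VB/ADJ/ADV)."""
    values = [
        informativeness(tok.surface, table)
        for tok in phrase_tokens
        if tok.tag in CONTENT_TAGS
    ]
    if not values:
        raise ValueError("phrase has no content word")
    return float(sum(values) / len(values))


def mention_tokens(mention_surface: str) -> list[TaggedToken]:
    """Tag a raw mention's tokens with the coarse closed-class heuristic
    (function words PREP/DET/OTHER, everything else NN) so that multi-token
    mentions can be averaged like harvested phrases."""
    toks = tokenize(mention_surface)
    if not toks:
        raise ValueError(f"mention {mention_surface!r} has no word tokens")
    return [
        TaggedToken(surface=surf, tag=guess_tag(surf), char_start=s, char_end=e)
        for surf, s, e in toks
    ]


def final_score(sim_target: float, csim: float, alpha: float = 0.5) -> float:
    """Convex combination ``alpha*sim_target + (1-alpha)*csim``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * sim_target + (1.0 - alpha) * csim


def filter_simpler(candidates, target_ci: float) -> list:
    """Candidates strictly less informative than the target, order kept.

    The inequality is strict: a candidate exactly as informative as the
    original term is no simplification.
    """
    return [c for c in candidates if c.informativeness < target_ci]
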