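"""Shared text primitives: normalization, tokenization, sentence splitting.

All vocabulary comparisons in the package go through :func:`normalize`
(Unicode NFC + lowercasing, accents preserved — Spanish "náuseas" and
"nauseas" stay distinct). Word tokens are maximal runs of Unicode letters,
optionally joined by internal hyphens; digits and punctuation never start
or extend a token, so "dolor" cannot fire inside "dolor33" or "dolores"
is handled at the token level by the matcher.
"""

from __future__ import annotations

import re
import unicodedata
from typing import Iterator

# Unicode letter runs with optional internal hyphens ("anti-inflamatorio").
_WORD_RE = re.compile(r"[^\W\d_]+(?:-[^\W\d_]+)*")


def normalize(text: str) -> str:
    """NFC-normalize and lowercase; accents are preserved."""
    return unicodedata.normalize("NFC", text).lower()


def collapse_ws(text: str) -> str:
    """Normalization used for gold-standard comparison: NFC, lowercase,
    runs of whitespace collapsed to single spaces, outer whitespace stripped."""
    return " ".join(normalize(text).split())


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Word tokens as ``(surface, char_start, char_end)`` triples.

    Offsets are 0-based half-open codepoint positions into ``text``.
    """
    return [(m.group(0), m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def iter_sentences(text: str) -> Iterator[tuple[int, int]]:
    """Yield ``(start, end)`` spans of sentences.

    Deliberately simple rule: a sentence ends at '.', '?' or '!' followed by
    whitespace and an uppercase letter. Pre-split input (one sentence per
    call) bypasses this entirely.
    """
    start = 0
    i = 0
    n = len(text)
    while i < n:
        if text[i] in ".?!":
            j = i + 1
            while j < n and text[j] in ".?!":
                j += 1
            k = j
            while k < n and text[k].isspace():
                k += 1
            if k > j and k < n and text[k].isupper():
                yield (start, j)
                start = k
                i = k
                continue
            i = j
        else:
            i += 1
    if start < n:
        yield (start, n)


def sentence_index_of(offset: int, spans: list[tuple[int, int]]) -> int:
    for idx, (s, e) in enumerate(spans):
        if s <= offset < e:
            return idx
    return max(0, len(spans) - 1)


# Small closed-class list used only to tag untagged mention tokens so that
# phrase averaging can skip function words. Anything not listed is treated
# as a content noun, the safe default for gazetteer entries.
_FUNCTION_TAGS: dict[str, str] = {
    **{w: "PREP" for w in (
        "de", "del", "al", "a", "en", "con", "por", "para", "sin",
        "sobre", "entre", "hacia", "ante", "bajo", "tras", "desde", "hasta",
    )},
    **{w: "DET" for w in (
        "el", "la", "los", "las", "un", "una", "unos", "unas",
        "este", "esta", "estos", "estas",
    )},
    **{w: "OTHER" for w in ("y", "o", "u", "e", "que", "se", "no", "ni")},
}


def guess_tag(surface: str) -> str:
    """Coarse tag for an untagged token: closed-class lookup, else NN."""
    return _FUNCTION_TAGS.get(normalize(surface), "NN")
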