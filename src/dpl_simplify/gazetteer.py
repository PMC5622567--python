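"""Dictionary-based recognition of adverse-drug-effect mentions.

A :class:`Lexicon` is a flat term list (one term per line, or a two-column
TSV with a canonical form). Matching is greedy left-to-right longest match
over normalized token sequences: case-insensitive, accent-preserving, and
strictly token-bounded — "dolor" never fires inside "dolores". Overlapping
shorter matches are suppressed; when several lexicons carry the same term,
the earliest lexicon in the sequence is credited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._text import iter_sentences, normalize, sentence_index_of, tokenize


@dataclass
class Lexicon:
    """A named gazetteer of (possibly multi-token) terms."""

    name: str
    entries: dict[tuple[str, ...], str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(all(tok for tok in key) and key for key in self.entries):
            raise ValueError("lexicon contains an empty entry")
        self.max_tokens = max((len(k) for k in self.entries), default=0)
        # token-level vocabulary, used by the phrase-harvest anchor rule
        self.word_set: frozenset[str] = frozenset(
            tok for key in self.entries for tok in key
        )

    @classmethod
    def from_terms(cls, name: str, terms) -> "Lexicon":
        entries: dict[tuple[str, ...], str | None] = {}
        for term in terms:
            canonical = None
            if isinstance(term, tuple):
                term, canonical = term
            key = tuple(normalize(term).split())
            if key and key not in entries:
                entries[key] = canonical
        return cls(name, entries)

    def canonical(self, term: str) -> str | None:
        return self.entries.get(tuple(normalize(term).split()))

    def __contains__(self, term: str) -> bool:
        return tuple(normalize(term).split()) in self.entries

    def contains_word(self, word: str) -> bool:
        """True if ``word`` occurs as a token of any entry (anchor rule)."""
        return normalize(word) in self.word_set

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EffectMention:
    """A recognized adverse-effect span with character offsets."""

    surface: str
    char_start: int
    char_end: int
    sentence_index: int
    matched_entry: str
    lexicon_name: str


def load_lexicon(path, name: str) -> Lexicon:
    """Read a UTF-8 term list: one term per line or ``term<TAB>canonical``.

    Blank lines and lines starting with ``#`` are skipped; an empty
    resulting lexicon is an error.
    """
    terms: list[tuple[str, str | None]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                term, canonical = line.split("\t", 1)
                terms.append((term.strip(), canonical.strip() or None))
            else:
                terms.append((line.strip(), None))
    lex = Lexicon.from_terms(name, terms)
    if len(lex) == 0:
        raise ValueError(f"lexicon {name!r} from {path} is empty")
    return lex


def save_lexicon(lexicon: Lexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(lexicon.entries):
            canonical = lexicon.entries[key]
            term = " ".join(key)
            fh.write(f"{term}\t{canonical}\n" if canonical else f"{term}\n")


def match_effects(text: str, lexicons) -> list[EffectMention]:
    """Greedy left-to-right longest-match mention recognition.

    Returns non-overlapping mentions sorted by ``char_start``; for equal
    spans the earliest lexicon in ``lexicons`` wins.
    """
    if not text:
        raise ValueError("match_effects requires nonempty text")
    tokens = tokenize(text)
    norm = [normalize(surf) for surf, _, _ in tokens]
    sent_spans = list(iter_sentences(text))
    max_len = max((lex.max_tokens for lex in lexicons), default=0)
    mentions: list[EffectMention] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for length in range(min(max_len, n - i), 0, -1):
            key = tuple(norm[i : i + length])
            for lex in lexicons:
                if key in lex.entries:
                    hit = (length, key, lex)
                    break
            if hit:
                break
        if hit is None:
            i += 1
            continue
        length, key, lex = hit
        start = tokens[i][1]
        end = tokens[i + length - 1][2]
        mentions.append(
            EffectMention(
                surface=text[start:end],
                char_start=start,
                char_end=end,
                sentence_index=sentence_index_of(start, sent_spans),
                matched_entry=" ".join(key),
                lexicon_name=lex.name,
            )
        )
        i += length
    return mentions
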