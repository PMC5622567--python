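"""End-to-end leaflet simplification and gold-standard evaluation.

For each recognized adverse-effect mention the pipeline (1) looks up or
averages its embedding, (2) gathers candidates — the top-k nearest single
words plus every harvested phrase — (3) ranks them by a convex combination
of target similarity and context similarity, (4) keeps only candidates
strictly less informative than the original term, and (5) splices the best
survivor into the text. Each step's outcome is recorded so a reviewer can
audit why a term was or was not replaced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import yaml

from ._text import collapse_ws, normalize
from .embeddings import EmbeddingModel, cosine, nearest_neighbors, phrase_vector
from .gazetteer import EffectMention, match_effects
from .phrases import PhraseStore
from .scoring import (
    Candidate,
    ContextWindow,
    FrequencyTable,
    build_context_window,
    context_similarity,
    filter_simpler,
    final_score,
    informativeness,
    mention_tokens,
    phrase_informativeness,
)

#: Closed set of per-mention outcomes.
REASONS = ("substituted", "no-candidates", "none-simpler", "target-oov")


@dataclass
class SimplifyConfig:
    """Tunable parameters of the simplification pipeline.

    window_size: context tokens taken on each side of a mention.
    top_k: nearest single-word neighbors considered as candidates.
    alpha: weight of target similarity vs context similarity in the rank.
    allow_det_after_prep: let one determiner intervene after a preposition
        in phrase patterns ("trastornos de la alimentación").
    pos_constraint: optionally drop word candidates sharing a crude stem
        (4-character prefix) with the target, off by default.
    skip_multiword_mentions: treat multi-token mentions as unresolvable
        instead of averaging their content words into a phrase vector.
    """

    window_size: int = 3
    top_k: int = 10
    alpha: float = 0.5
    allow_det_after_prep: bool = True
    pos_constraint: bool = False
    skip_multiword_mentions: bool = False

    @classmethod
    def from_yaml(cls, path) -> "SimplifyConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimplificationResult:
    """Per-mention outcome with the ranked candidate trace kept for audit."""

    doc_id: str
    mention: EffectMention
    substitute: str | None
    reason: str
    candidate_trace: list[Candidate] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if (self.substitute is None) != (self.reason != "substituted"):
            raise ValueError("substitute must be set iff reason == 'substituted'")

    @property
    def proposed(self) -> str:
        """What the system proposes for this span: the substitute, or the
        original surface when the mention was kept."""
        return self.substitute if self.substitute is not None else self.mention.surface

    def to_record(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "char_start": self.mention.char_start,
            "char_end": self.mention.char_end,
            "surface": self.mention.surface,
            "matched_entry": self.mention.matched_entry,
            "lexicon": self.mention.lexicon_name,
            "substitute": self.substitute,
            "reason": self.reason,
        }


@dataclass(frozen=True)
class GoldRecord:
    """A human-annotated simplest synonym for one effect span."""

    doc_id: str
    char_start: int
    char_end: int
    effect: str
    gold_synonym: str
    alternatives: tuple[str, ...] = ()


def _target_vector_and_ci(mention, model, table, config):
    """Embedding and informativeness of the mention; (None, None) on OOV."""
    toks = mention_tokens(mention.surface)
    if len(toks) > 1 and config.skip_multiword_mentions:
        return None, None
    if len(toks) == 1:
        vec = model.get(toks[0].surface)
        if vec is None:
            return None, None
        return vec, informativeness(toks[0].surface, table)
    vec = phrase_vector(model, toks)
    if vec is None:
        return None, None
    return vec, phrase_informativeness(toks, table)


def _crude_stem(word: str) -> str:
    return normalize(word)[:4]


def simplify_mention(
    mention: EffectMention,
    window: ContextWindow,
    model: EmbeddingModel,
    store: PhraseStore | None,
    table: FrequencyTable,
    config: SimplifyConfig | None = None,
    doc_id: str = "",
) -> SimplificationResult:
    """Choose the best simpler substitute for one mention, or keep it.

    Candidates are the top-k nearest word neighbors of the mention vector
    (the mention's own surface forms excluded) together with every stored
    phrase scored by cosine to the mention vector. Deterministic given
    fixed inputs: ties are resolved lexicographically.
    """
    config = config or SimplifyConfig()
    tvec, target_ci = _target_vector_and_ci(mention, model, table, config)
    if tvec is None:
        return SimplificationResult(doc_id, mention, None, "target-oov")

    own_forms = {normalize(mention.surface)} | {
        t.key for t in mention_tokens(mention.surface)
    }
    candidates: list[Candidate] = []
    if config.top_k > 0:
        stems = {_crude_stem(t.surface) for t in mention_tokens(mention.surface)}
        for word, sim in nearest_neighbors(
            model, tvec, k=config.top_k, exclude=own_forms
        ):
            if config.pos_constraint and _crude_stem(word) in stems:
                continue
            vec = model[word]
            csim = context_similarity(vec, window, model)
            ci = informativeness(word, table)
            candidates.append(
                Candidate(
                    text=word,
                    vector=vec,
                    sim_target=sim,
                    csim=csim,
                    informativeness=ci,
                    final_score=final_score(sim, csim, config.alpha),
                    is_phrase=False,
                )
            )
    if store is not None:
        for text, entry in store.items():
            if normalize(text) in own_forms:
                continue
            sim = cosine(entry.vector, tvec)
            csim = context_similarity(entry.vector, window, model)
            ci = phrase_informativeness(entry.tokens, table)
            candidates.append(
                Candidate(
                    text=text,
                    vector=entry.vector,
                    sim_target=sim,
                    csim=csim,
                    informativeness=ci,
                    final_score=final_score(sim, csim, config.alpha),
                    is_phrase=True,
                )
            )
    candidates.sort(key=lambda c: (-c.final_score, c.text))
    if not candidates:
        return SimplificationResult(doc_id, mention, None, "no-candidates")
    survivors = filter_simpler(candidates, target_ci)
    if not survivors:
        return SimplificationResult(
            doc_id, mention, None, "none-simpler", candidate_trace=candidates
        )
    best = survivors[0]
    return SimplificationResult(
        doc_id, mention, best.text, "substituted", candidate_trace=candidates
    )


def simplify_document(
    text: str,
    model: EmbeddingModel,
    lexicons,
    table: FrequencyTable,
    store: PhraseStore | None = None,
    config: SimplifyConfig | None = None,
    doc_id: str = "doc",
) -> tuple[list[SimplificationResult], str]:
    """Simplify every recognized mention in a document.

    Returns the per-mention results (in document order) and the rewritten
    text with substitutes spliced in right-to-left, so earlier offsets stay
    valid; all non-mention text is unchanged byte for byte.
    """
    config = config or SimplifyConfig()
    if not text:
        return [], text
    mentions = match_effects(text, lexicons)
    results: list[SimplificationResult] = []
    for mention in mentions:
        window = build_context_window(text, mention, model, config.window_size)
        results.append(
            simplify_mention(mention, window, model, store, table, config, doc_id)
        )
    rewritten = text
    for res in reversed(results):
        if res.substitute is not None:
            m = res.mention
            rewritten = rewritten[: m.char_start] + res.substitute + rewritten[m.char_end :]
    return results, rewritten


@dataclass
class AccuracyReport:
    """Match counts against a gold standard, split by synonym arity."""

    n_gold: int
    n_correct: int
    n_gold_uni: int
    n_correct_uni: int
    n_gold_multi: int
    n_correct_multi: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_gold if self.n_gold else 0.0

    @property
    def accuracy_uni(self) -> float:
        return self.n_correct_uni / self.n_gold_uni if self.n_gold_uni else 0.0

    @property
    def accuracy_multi(self) -> float:
        return self.n_correct_multi / self.n_gold_multi if self.n_gold_multi else 0.0

    def to_dict(self) -> dict:
        return {
            "n_gold": self.n_gold,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "uni_word": {
                "n_gold": self.n_gold_uni,
                "n_correct": self.n_correct_uni,
                "accuracy": self.accuracy_uni,
            },
            "multi_word": {
                "n_gold": self.n_gold_multi,
                "n_correct": self.n_correct_multi,
                "accuracy": self.accuracy_multi,
            },
        }


def evaluate_accuracy(
    results,
    gold,
    multi_reference: bool = False,
) -> AccuracyReport:
    """Accuracy of proposed substitutes against gold synonyms.

    Results and gold records join on (doc_id, char_start, char_end). A
    match is normalized string equality (NFC, lowercase, collapsed
    whitespace) between the system's proposal — the substitute, or the kept
    original — and the gold synonym; gold spans with no system result count
    as failures. The report also splits accuracy over uni-word vs
    multi-word gold synonyms. With ``multi_reference`` on, any listed
    alternative synonym also counts as a match (off by default).
    """
    by_key: dict[tuple, SimplificationResult] = {}
    for res in results:
        by_key[(res.doc_id, res.mention.char_start, res.mention.char_end)] = res
    seen: set[tuple] = set()
    n_uni = n_multi = c_uni = c_multi = 0
    for record in gold:
        key = (record.doc_id, record.char_start, record.char_end)
        if key in seen:
            raise ValueError(f"duplicate gold key {key}")
        seen.add(key)
        accepted = {collapse_ws(record.gold_synonym)}
        if multi_reference:
            accepted |= {collapse_ws(a) for a in record.alternatives}
        res = by_key.get(key)
        correct = res is not None and collapse_ws(res.proposed) in accepted
        if len(record.gold_synonym.split()) == 1:
            n_uni += 1
            c_uni += int(correct)
        else:
            n_multi += 1
            c_multi += int(correct)
    return AccuracyReport(
        n_gold=n_uni + n_multi,
        n_correct=c_uni + c_multi,
        n_gold_uni=n_uni,
        n_correct_uni=c_uni,
        n_gold_multi=n_multi,
        n_correct_multi=c_multi,
    )


# ---------------------------------------------------------------------------
# JSON-lines I/O


def write_results_jsonl(results, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for res in results:
            fh.write(json.dumps(res.to_record(), ensure_ascii=False, sort_keys=True) + "\n")


def read_results_jsonl(path) -> list[SimplificationResult]:
    """Rehydrate results (without candidate traces) for evaluation."""
    results: list[SimplificationResult] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            mention = EffectMention(
                surface=obj["surface"],
                char_start=obj["char_start"],
                char_end=obj["char_end"],
                sentence_index=0,
                matched_entry=obj.get("matched_entry", obj["surface"]),
                lexicon_name=obj.get("lexicon", ""),
            )
            results.append(
                SimplificationResult(
                    doc_id=obj["doc_id"],
                    mention=mention,
                    substitute=obj["substitute"],
                    reason=obj["reason"],
                )
            )
    return results


def read_gold_jsonl(path) -> list[GoldRecord]:
    gold: list[GoldRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            gold.append(
                GoldRecord(
                    doc_id=obj["doc_id"],
                    char_start=obj["char_start"],
                    char_end=obj["char_end"],
                    effect=obj["effect"],
                    gold_synonym=obj["gold_synonym"],
                    alternatives=tuple(obj.get("alternatives", ())),
                )
            )
    return gold


def write_gold_jsonl(gold, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in gold:
            obj = {
                "doc_id": rec.doc_id,
                "char_start": rec.char_start,
                "char_end": rec.char_end,
                "effect": rec.effect,
                "gold_synonym": rec.gold_synonym,
            }
            if rec.alternatives:
                obj["alternatives"] = list(rec.alternatives)
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")
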