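"""Self-contained synthetic test worlds.

:func:`make_world` plants, for each target term, a synonym whose vector is
close to the target's (cosine above a floor), distractors whose vectors are
far (cosine below a ceiling), and a background frequency table in which the
synonym is ``freq_ratio`` times more frequent — hence less informative —
than the target. Context words in each generated sentence lie nearer the
synonym than any distractor, so the full pipeline should recover exactly
the planted synonym for every target. The statistical structure emulates
what the method assumes of real embeddings: synonyms have close vectors
because they occur in similar contexts, and simpler words are more
frequent in a background corpus.

:func:`make_tagged_corpus` builds a tiny POS-tagged corpus instantiating
each stock noun-phrase pattern, with known ground truth for the harvester,
including negative controls (an unanchored phrase and an all-OOV phrase).
The pattern sentences reuse the canonical Spanish examples ("sueño
anormal", "enfermedad del estómago", "problemas para tragar", "azucar alta
en sangre", "trastornos de la alimentación") so the fixture doubles as
documentation.

All randomness flows from the single ``seed``; generation is fully
reproducible and uses bounded rejection sampling for the cosine
constraints (an infeasible floor/ceiling raises after a retry cap).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embeddings import EmbeddingModel, TaggedToken, save_embeddings
from .gazetteer import Lexicon, save_lexicon
from .pipeline import GoldRecord, write_gold_jsonl
from .scoring import FrequencyTable

_MAX_TRIES = 10_000


class FixtureError(RuntimeError):
    """The requested cosine geometry could not be sampled."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-synonym world."""

    n_targets: int = 100
    dimension: int = 16
    synonym_cosine_floor: float = 0.95
    distractor_cosine_ceiling: float = 0.5
    freq_ratio: float = 10.0
    seed: int = 0
    n_distractors: int = 3
    n_context: int = 3
    target_count: int = 100  # base frequency-table count of each target

    def __post_init__(self) -> None:
        if not self.synonym_cosine_floor > self.distractor_cosine_ceiling:
            raise ValueError("synonym floor must exceed distractor ceiling")
        if self.freq_ratio < 1:
            raise ValueError("freq_ratio must be >= 1")
        if self.n_targets < 1 or self.dimension < 2:
            raise ValueError("need n_targets >= 1 and dimension >= 2")
        if self.n_distractors < 3 or self.n_context < 3:
            raise ValueError("need >= 3 distractors and >= 3 context words")


@dataclass
class World:
    """Everything the pipeline needs, generated from one seed."""

    spec: FixtureSpec
    model: EmbeddingModel
    table: FrequencyTable
    lexicon: Lexicon
    gold: list[GoldRecord]
    documents: dict[str, str]
    synonym_of: dict[str, str] = field(default_factory=dict)


def _alpha(i: int) -> str:
    """Letters-only base-26 encoding; fixture words must stay digit-free
    because the tokenizer only accepts letter runs."""
    letters = string.ascii_lowercase
    out = letters[i % 26]
    i //= 26
    while i:
        out = letters[i % 26] + out
        i //= 26
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise FixtureError("degenerate zero sample")
    return v / n


def _sample_near(rng, base: np.ndarray, cos_min: float, cos_max: float = 1.0):
    """Rejection-sample a unit vector with cosine to ``base`` in range.

    The proposal perturbs ``base`` with isotropic noise scaled so the
    expected cosine sits near ``cos_min``; acceptance is then checked
    exactly. Raises :class:`FixtureError` after the retry cap.
    """
    d = base.size
    level = min(max(cos_min, 1e-3), 0.999)
    sigma = np.sqrt(max(1.0 / level**2 - 1.0, 1e-6) / d)
    for _ in range(_MAX_TRIES):
        v = _unit(base + sigma * rng.standard_normal(d))
        c = float(v @ base)
        if cos_min <= c <= cos_max:
            return v, c
    raise FixtureError(
        f"could not sample a vector with cosine in [{cos_min}, {cos_max}] "
        f"in dimension {d} within {_MAX_TRIES} attempts"
    )


def _sample_far(rng, base: np.ndarray, cos_max: float) -> np.ndarray:
    d = base.size
    for _ in range(_MAX_TRIES):
        v = _unit(rng.standard_normal(d))
        if float(v @ base) <= cos_max:
            return v
    raise FixtureError(
        f"could not sample a vector with cosine <= {cos_max} in dimension {d}"
    )


def make_world(spec: FixtureSpec) -> World:
    """Generate a planted-synonym world (model, table, lexicon, gold, docs)."""
    rng = np.random.default_rng(spec.seed)
    vectors: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    gold: list[GoldRecord] = []
    documents: dict[str, str] = {}
    synonym_of: dict[str, str] = {}
    terms: list[str] = []

    for i in range(spec.n_targets):
        tag = _alpha(i)
        target = f"efecto{tag}"
        synonym = f"molestia{tag}"
        tvec = _unit(rng.standard_normal(spec.dimension))
        svec, syn_cos = _sample_near(rng, tvec, spec.synonym_cosine_floor)
        distractors = {}
        for j in range(spec.n_distractors):
            distractors[f"ruido{tag}{_alpha(j)}"] = _sample_far(
                rng, tvec, spec.distractor_cosine_ceiling
            )
        # context words: near the synonym, strictly farther from the target
        # than the synonym is (so the synonym stays the top-1 neighbor), and
        # nearer the synonym than any distractor
        context = {}
        dvecs = list(distractors.values())
        for j in range(spec.n_context):
            for _ in range(_MAX_TRIES):
                cvec, _ = _sample_near(rng, svec, 0.6)
                if float(cvec @ tvec) >= syn_cos - 0.02:
                    continue
                if all(float(cvec @ dv) < float(cvec @ svec) for dv in dvecs):
                    break
            else:
                raise FixtureError("could not place a context word")
            context[f"contexto{tag}{_alpha(j)}"] = cvec

        vectors[target] = tvec
        vectors[synonym] = svec
        vectors.update(distractors)
        vectors.update(context)
        counts[target] = spec.target_count
        counts[synonym] = int(round(spec.freq_ratio * spec.target_count))
        for w in (*distractors, *context):
            counts[w] = max(1, spec.target_count // 10)

        cwords = sorted(context)
        doc = f"{cwords[0]} {cwords[1]} {target} {' '.join(cwords[2:])}."
        start = doc.index(target)
        doc_id = f"doc{tag}"
        documents[doc_id] = doc
        gold.append(
            GoldRecord(
                doc_id=doc_id,
                char_start=start,
                char_end=start + len(target),
                effect=target,
                gold_synonym=synonym,
            )
        )
        synonym_of[target] = synonym
        terms.append(target)

    model = EmbeddingModel(spec.dimension, vectors)
    return World(
        spec=spec,
        model=model,
        table=FrequencyTable(counts),
        lexicon=Lexicon.from_terms("planted-effects", terms),
        gold=gold,
        documents=documents,
        synonym_of=synonym_of,
    )


# ---------------------------------------------------------------------------
# Tagged corpus with known harvest ground truth


@dataclass
class TaggedCorpusWorld:
    sentences: list[list[TaggedToken]]
    anchor: Lexicon
    model: EmbeddingModel
    manifest: frozenset[str]          # phrases a correct harvest must keep
    expected_rejections: dict[str, int]

    def corpus_text(self) -> str:
        """token<TAB>tag TSV, blank line between sentences."""
        blocks = [
            "\n".join(f"{tok.surface}\t{tok.tag}" for tok in sent)
            for sent in self.sentences
        ]
        return "\n\n".join(blocks) + "\n"


_PATTERN_SENTENCES: list[list[tuple[str, str]]] = [
    [("sueño", "NN"), ("anormal", "ADJ")],
    [("enfermedad", "NN"), ("del", "PREP"), ("estómago", "NN")],
    [("problemas", "NN"), ("para", "PREP"), ("tragar", "VB")],
    [("azucar", "NN"), ("alta", "ADJ"), ("en", "PREP"), ("sangre", "NN")],
    [("trastornos", "NN"), ("de", "PREP"), ("la", "DET"), ("alimentación", "NN")],
    # negative controls
    [("ruido", "NN"), ("extraño", "ADJ")],          # patterned but unanchored
    [("dolor", "NN"), ("fantasmal", "ADJ")],        # anchored but fully OOV
    [("muy", "ADV"), ("anormal", "ADJ")],           # headless: no match at all
    [("sueño", "NN"), ("anormal", "ADJ")],          # duplicate of sentence 1
]

_ANCHOR_WORDS = ("sueño", "enfermedad", "problemas", "azucar", "trastornos", "dolor")

#: vocabulary of the tagged-corpus model; "dolor"/"fantasmal" stay OOV
_CORPUS_VOCAB = (
    "sueño", "anormal", "enfermedad", "estómago", "problemas", "tragar",
    "azucar", "alta", "sangre", "trastornos", "alimentación",
    "ruido", "extraño",
)


def make_tagged_corpus(spec: FixtureSpec) -> TaggedCorpusWorld:
    """A tiny tagged corpus with one harvestable phrase per stock pattern,
    plus an unanchored phrase, an all-OOV phrase, a headless bigram and a
    duplicate — so the expected harvest outcome is known exactly."""
    rng = np.random.default_rng(spec.seed + 1)
    vectors = {
        w: _unit(rng.standard_normal(spec.dimension)) for w in _CORPUS_VOCAB
    }
    sentences = [
        [TaggedToken(surface=s, tag=t) for s, t in sent]
        for sent in _PATTERN_SENTENCES
    ]
    return TaggedCorpusWorld(
        sentences=sentences,
        anchor=Lexicon.from_terms("anchor", _ANCHOR_WORDS),
        model=EmbeddingModel(spec.dimension, vectors),
        manifest=frozenset(
            {
                "sueño anormal",
                "enfermedad del estómago",
                "problemas para tragar",
                "azucar alta en sangre",
                "trastornos de la alimentación",
            }
        ),
        expected_rejections={"no-anchor": 1, "oov": 1, "duplicate": 1},
    )


def write_world(world: World, outdir) -> dict[str, str]:
    """Write a world in the exact on-disk formats the CLI consumes.

    Returns a mapping of artifact names to paths: embeddings (word2vec
    text), lexicon/frequency TSV, per-document text files, gold JSON lines.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "embeddings": str(out / "embeddings.txt"),
        "lexicon": str(out / "lexicon.tsv"),
        "freq": str(out / "freq.tsv"),
        "gold": str(out / "gold.jsonl"),
        "docs": str(out / "docs"),
    }
    save_embeddings(world.model, paths["embeddings"])
    save_lexicon(world.lexicon, paths["lexicon"])
    world.table.save(paths["freq"])
    write_gold_jsonl(world.gold, paths["gold"])
    docdir = out / "docs"
    docdir.mkdir(exist_ok=True)
    for doc_id, text in world.documents.items():
        (docdir / f"{doc_id}.txt").write_text(text, encoding="utf-8")
    return paths


def write_tagged_corpus(world: TaggedCorpusWorld, outdir) -> dict[str, str]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": str(out / "corpus.tsv"),
        "anchor": str(out / "anchor.tsv"),
        "corpus_embeddings": str(out / "corpus_embeddings.txt"),
    }
    Path(paths["corpus"]).write_text(world.corpus_text(), encoding="utf-8")
    save_lexicon(world.anchor, paths["anchor"])
    save_embeddings(world.model, paths["corpus_embeddings"])
    return paths
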