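# Methods

## The simplification procedure

`dpl-simplify` replaces adverse-drug-effect terms in Spanish drug package
leaflets (the patient-facing prospecto) with simpler synonyms. The method
needs no synonym dictionary: candidates come from the geometry of a word
embedding space, and "simpler" is operationalized as "more frequent in a
large background corpus". The pipeline is:

1. **Mention recognition.** Adverse-effect terms are found by
   dictionary lookup against one or more gazetteers (in practice,
   MedDRA-LLT- or MedlinePlus-style term lists). Matching is greedy
   left-to-right longest match over normalized token sequences:
   case-insensitive, accent-preserving, and strictly token-bounded, so
   *dolor* never fires inside *dolores*. When several gazetteers carry the
   same term, the earliest one in the user's ordering is credited — the
   overlap-resolution policy is a package convention, since nothing forces
   a particular choice.

2. **Candidate generation.** For a mention with embedding `v_w`, the
   candidates are (a) its `top_k` nearest vocabulary words by cosine
   similarity (its own surface forms excluded) and (b) every phrase in a
   pre-harvested phrase store, scored by cosine between the phrase
   embedding and `v_w`. Multi-token mentions get their vector by averaging
   the embeddings of their content words (nouns, lexical verbs,
   adjectives, adverbs), the same composition used for phrases; a flag
   (`skip_multiword_mentions`) disables this and leaves such mentions
   untouched instead.

3. **Ranking.** Each candidate `s` is scored by

   `score(s) = α · cos(v_s, v_w) + (1 − α) · csim(s, w)`,

   where `csim(s, w) = (1/|C(w)|) Σ_{w′∈C(w)} cos(v_s, v_{w′})` is the
   mean cosine between the candidate and the words in a context window
   `C(w)` of `window_size` tokens on each side of the mention, clipped at
   sentence boundaries, with the mention's own tokens excluded and
   out-of-vocabulary tokens skipped. Context similarity guards against
   substituting a synonym of the wrong sense of a polysemous word. The
   convex combination with default α = 0.5 is a design choice of this
   package: both similarities matter, and a single weight keeps the
   trade-off auditable and configurable. An empty context contributes 0,
   neither supporting nor penalizing the candidate.

4. **The simpler-than filter.** A word's informativeness is

   `ci(w) = −log((freq(w) + 1) / (N + 1))`

   with `freq` from a background frequency table (Google-Books-Ngram-style
   word/count TSV) and `N` its total mass. The log is natural — the base
   only rescales, never reorders. Reading the denominator as the *total*
   mass plus one keeps the argument ≤ 1, so ci ≥ 0, zero exactly for a
   word carrying the whole mass, and strictly decreasing in frequency.
   Phrases take the mean ci of their content words. A candidate may
   replace the original term only if its informativeness is **strictly**
   lower: a candidate exactly as rare as the original is no
   simplification. Terms that are already simple (very frequent) are
   handled by this filter alone — there is no separate whitelist of easy
   words, so "no candidate survives" is a first-class outcome
   (`none-simpler`), as is an out-of-vocabulary mention (`target-oov`).

5. **Substitution.** The best surviving candidate is spliced into the
   text. Splices are applied right-to-left so earlier offsets stay valid;
   non-mention text is unchanged byte for byte. Ties anywhere in the
   ranking are broken lexicographically, so identical inputs always
   produce byte-identical output.

## Phrase harvesting

Nearly half of human-chosen simplest synonyms are multi-word, which pure
word embeddings cannot propose. The harvester scans a POS-tagged corpus
for noun phrases matching four NN-headed tag patterns — NN ADJ (*sueño
anormal*), NN PREP NN (*enfermedad del estómago*), NN PREP VB (*problemas
para tragar*), NN ADJ PREP NN (*azucar alta en sangre*) — and keeps a
phrase only if at least one of its tokens belongs to an anchor lexicon
(emulating the MedDRA-membership constraint that keeps the harvest from
drowning in generic noun phrases) and its content words yield a non-OOV
phrase embedding. The pattern set is configurable; the four stock patterns
are the printed inventory this package commits to. Two extensions are
package decisions: a single determiner may intervene after a preposition
(`allow_det_after_prep`, default on) — without it *trastornos de la
alimentación* cannot match NN PREP NN — and when several patterns match at
one position the longest span wins, ties going to pattern order. Spanish
contractions *del*/*al* are treated as single PREP tokens. The harvester
consumes pre-tagged `token<TAB>tag` TSV plus an optional tagset-mapping
file, decoupling it from any particular tagger; unmapped tags degrade to
OTHER and unreadable lines are skipped with a warning, never aborting.

## Normalization and numeric conventions

- All vocabulary lookups are Unicode NFC + lowercase with accents
  preserved (*náuseas* ≠ *nauseas*); the embedding model is assumed
  lowercased, and results on a cased model would differ.
- Word tokens are maximal runs of Unicode letters with optional internal
  hyphens; sentence splitting is the deliberately simple
  terminator-then-capital rule, overridable by pre-split input.
- A zero vector's cosine is defined as 0 with a warning rather than an
  error, so one degenerate embedding cannot abort a batch run; OOV tokens
  are skipped and logged, never imputed, because imputation would silently
  distort the context-similarity averages.
- Untagged mention tokens are coarse-tagged by a small closed-class
  Spanish function-word list (prepositions, determiners, conjunctions);
  everything else defaults to NN, the safe assumption for gazetteer
  entries.
- Gold-standard evaluation joins system results to annotations on
  (document, character span) and requires normalized string equality
  (NFC, lowercase, collapsed whitespace) between the system's proposal —
  substitute, or kept original — and the gold synonym; accuracy is also
  split over uni-word vs multi-word gold synonyms. An optional
  multi-reference mode accepts any listed alternative, off by default
  because a single gold answer is the stricter, standard protocol.

## Synthetic worlds

`dpl_simplify.fixtures` generates complete, seeded test worlds in the
exact on-disk formats the CLI reads. `make_world` plants, per target, a
synonym vector with cosine above `synonym_cosine_floor` (default 0.95),
at least three distractors below `distractor_cosine_ceiling` (default
0.5), and a frequency table where the synonym is `freq_ratio` (default
10) times more frequent than the target; each generated sentence embeds
the target among at least three context words sampled to lie nearer the
synonym than any distractor and strictly farther from the target than the
synonym is. Distractor and context words are rarer than the target, so
the informativeness filter removes them even when they rank. By
construction the pipeline should recover exactly the planted synonym;
the defaults (100 targets, dimension 16) make that run take well under a
minute. Cosine constraints are met by bounded rejection sampling (10,000
attempts per vector, proposal noise scaled to the requested cosine
level); an infeasible floor/ceiling raises rather than looping.

What the generator does **not** emulate: real Spanish morphology,
polysemy, leaflet discourse, tokenization noise, or the long-tailed
frequency structure of a real n-gram corpus. Passing the planted-recovery
test therefore shows the machinery is correct — candidate generation,
ranking, filtering, splicing, evaluation — not that the method reaches
any particular accuracy on real leaflets, which depends on external
resources (a large pre-trained embedding model, real gazetteers, real
n-gram counts) deliberately outside this package's scope.

`make_tagged_corpus` builds a nine-sentence tagged corpus with one
harvestable phrase per stock pattern (reusing the canonical Spanish
examples, so the fixture doubles as documentation), an unanchored phrase,
an anchored but fully OOV phrase, a headless bigram and a duplicate —
giving the harvester a known, exact expected outcome including its
rejection accounting.

## Parameters at a glance

| parameter | default | meaning |
|---|---|---|
| `window_size` | 3 | context tokens per side of a mention (sentence-clipped) |
| `top_k` | 10 | nearest-word candidates per mention |
| `alpha` | 0.5 | weight of target vs context similarity |
| `allow_det_after_prep` | true | let one DET follow a PREP inside patterns |
| `pos_constraint` | false | drop word candidates sharing a crude 4-char stem with the target |
| `skip_multiword_mentions` | false | leave multi-token mentions unresolved instead of averaging |

## Known limitations

- Candidates are only as good as the embedding model; nothing prevents an
  antonym with a close vector from being proposed.
- Phrase informativeness as the mean ci of content words is a pragmatic
  extension — the word-level formula does not define a phrase value — and
  makes long frequent-word phrases look simple.
- The gazetteer does no morphological expansion; plural/gender variants
  must be listed explicitly.
- Only the word2vec *text* format is read (no binary, no subword
  composition).
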