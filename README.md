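# dpl-simplify

Lexical simplification of adverse-drug-effect terms in drug package
leaflets (prospectos), for researchers in biomedical text mining and
health-literacy tooling. Patients routinely misread the side-effects
section of a leaflet; this package replaces specialist effect terms with
simpler synonyms chosen from a word-embedding space, with no synonym
dictionary required.

## Method

For each adverse-effect mention *w* found by gazetteer lookup, candidates
*s* are the top-*k* nearest words by cosine similarity plus a store of
harvested noun phrases (embedded as the mean vector of their content
words). Candidates are ranked by

    score(s) = α · cos(v_s, v_w) + (1 − α) · csim(s, w)

    csim(s, w) = (1 / |C(w)|) · Σ_{w′ ∈ C(w)} cos(v_s, v_{w′})

where C(w) is a window of three tokens on each side of the mention —
context similarity keeps the ranking from drifting to a synonym of the
wrong sense. A candidate may replace the original term only if it is
strictly less informative,

    ci(w) = −log((freq(w) + 1) / (N + 1)),

with freq taken from a background frequency table of total mass N: rarer
words are assumed more complex, so simplification means moving down the
informativeness scale. Everything else — longest-match NER, NN-headed POS
patterns for phrase harvesting with an anchor-lexicon constraint,
right-to-left splicing, gold-standard accuracy evaluation — is documented
in [docs/methods.md](docs/methods.md).

## Worked example

The package ships a seeded generator of complete synthetic worlds, so the
whole pipeline runs without any downloads:

```sh
$ dpl-simplify fixtures --out demo --seed 3 --n-targets 2
$ dpl-simplify run --text demo/docs/doca.txt --text demo/docs/docb.txt \
    --embeddings demo/embeddings.txt --lexicon demo/lexicon.tsv \
    --freq demo/freq.tsv --out demo/results.jsonl --rewrite-dir demo/rewritten
$ cat demo/results.jsonl
{"char_end": 29, "char_start": 22, "doc_id": "doca", "lexicon": "lexicon", "matched_entry": "efectoa", "reason": "substituted", "substitute": "molestiaa", "surface": "efectoa"}
{"char_end": 29, "char_start": 22, "doc_id": "docb", "lexicon": "lexicon", "matched_entry": "efectob", "reason": "substituted", "substitute": "molestiab", "surface": "efectob"}
$ dpl-simplify eval --results demo/results.jsonl --gold demo/gold.jsonl
{"accuracy": 1.0, "multi_word": {"accuracy": 0.0, "n_correct": 0, "n_gold": 0}, "n_correct": 2, "n_gold": 2, "uni_word": {"accuracy": 1.0, "n_correct": 2, "n_gold": 2}}
```

Each generated document plants one effect term (`efectoa`) whose synonym
(`molestiaa`) was constructed to be its nearest embedding neighbor and
ten times more frequent; the results show both mentions recognized at
their character spans and substituted (`"reason": "substituted"`), and
the evaluation reports 2/2 agreement with the generator's gold file. The
rewritten leaflet contains the substitute spliced in place:

```sh
$ cat demo/rewritten/doca.txt
contextoaa contextoab molestiaa contextoac.
```

A mention can also end as `none-simpler` (no candidate beats the
original's informativeness — common for already-simple terms like *dolor
de cabeza*), `no-candidates`, or `target-oov`.

The other subcommands are `dpl-simplify ner` (recognition only) and
`dpl-simplify harvest` (build a phrase store from a tagged corpus). All
parameters (`window_size`, `top_k`, `alpha`, `allow_det_after_prep`,
`pos_constraint`) sit in a YAML config passed with `--config`.

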