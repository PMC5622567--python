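"""Context similarity, informativeness, and the simpler-than filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpl_simplify.embeddings import EmbeddingModel, TaggedToken
from dpl_simplify.gazetteer import EffectMention
from dpl_simplify.scoring import (
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

from conftest import brute_cosine


def _mention(surface="efecto", start=0, end=6):
    return EffectMention(surface, start, end, 0, surface, "lex")


class TestContextSimilarity:
    def test_mean_of_cosines(self, toy_model):
        window = ContextWindow(_mention(), context_words=["a", "b"])
        # candidate along (1,0): cosines 1 and 0, mean 0.5
        assert context_similarity(np.array([1.0, 0.0]), window, toy_model) == (
            pytest.approx(0.5)
        )

    def test_identical_direction_gives_one(self, toy_model):
        window = ContextWindow(_mention(), context_words=["a", "sueño"])
        assert context_similarity(np.array([3.0, 0.0]), window, toy_model) == (
            pytest.approx(1.0)
        )

    def test_empty_context_zero(self, toy_model):
        window = ContextWindow(_mention(), context_words=[])
        assert context_similarity(np.array([1.0, 0.0]), window, toy_model) == 0.0


class TestContextWindow:
    def test_window_clipped_at_sentence_and_excludes_target(self):
        rng = np.random.default_rng(0)
        words = ["uno", "dos", "tres", "efecto", "cuatro", "cinco"]
        model = EmbeddingModel(3, {w: rng.normal(size=3) for w in words})
        text = "Antes aparte. Uno dos tres efecto cuatro cinco seis listo."
        start = text.index("efecto")
        mention = EffectMention("efecto", start, start + 6, 1, "efecto", "lex")
        window = build_context_window(text, mention, model, window_size=3)
        assert window.context_words == ["Uno", "dos", "tres", "cuatro", "cinco"]
        assert len(window.context_words) <= 6

    def test_oov_context_tokens_skipped(self, toy_model):
        text = "a desconocida b."
        mention = EffectMention("desconocida", 2, 13, 0, "desconocida", "lex")
        window = build_context_window(text, mention, toy_model)
        assert window.context_words == ["a", "b"]


class TestInformativeness:
    def test_whole_mass_word_is_zero(self):
        table = FrequencyTable({"common": 99, "rare": 0})
        assert informativeness("common", table) == pytest.approx(0.0, abs=1e-15)

    def test_rare_word_value(self):
        table = FrequencyTable({"common": 99, "rare": 0})
        assert informativeness("rare", table) == pytest.approx(math.log(100))

    def test_oov_equals_freq_zero(self):
        table = FrequencyTable({"common": 99, "rare": 0})
        assert informativeness("ausente", table) == informativeness("rare", table)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            informativeness("x", FrequencyTable({}))

    @settings(deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(["w" + c for c in "abcdefgh"]),
            st.integers(0, 10**9),
            min_size=2,
        )
    )
    def test_monotone_decreasing_in_frequency(self, counts):
        table = FrequencyTable(counts)
        if table.total == 0:
            return
        words = sorted(counts, key=counts.get)
        for w1, w2 in zip(words, words[1:]):
            if counts[w2] > counts[w1]:
                assert informativeness(w2, table) < informativeness(w1, table)
            assert informativeness(w1, table) >= 0.0

    def test_adding_occurrences_never_increases_ci(self):
        base = {"a": 5, "b": 7}
        for extra in (1, 10, 1000):
            grown = FrequencyTable({**base, "a": base["a"] + extra})
            assert informativeness("a", grown) <= informativeness(
                "a", FrequencyTable(base)
            )

    def test_table_load_and_total(self, tmp_path):
        path = tmp_path / "freq.tsv"
        path.write_text("# counts\ncasa\t10\nárbol\t5\n", encoding="utf-8")
        table = FrequencyTable.load(path)
        assert table.total == 15
        assert table.freq("CASA") == 10
        assert table.freq("ausente") == 0


class TestPhraseInformativeness:
    table = FrequencyTable({"sueño": 9, "anormal": 99, "del": 10**6})

    def test_single_content_word(self):
        toks = [TaggedToken("sueño", "NN")]
        assert phrase_informativeness(toks, self.table) == informativeness(
            "sueño", self.table
        )

    def test_mean_over_content_words(self):
        toks = [TaggedToken("sueño", "NN"), TaggedToken("anormal", "ADJ")]
        expected = (
            informativeness("sueño", self.table)
            + informativeness("anormal", self.table)
        ) / 2
        assert phrase_informativeness(toks, self.table) == pytest.approx(expected)

    def test_function_words_ignored(self):
        toks = [TaggedToken("sueño", "NN"), TaggedToken("del", "PREP")]
        assert phrase_informativeness(toks, self.table) == informativeness(
            "sueño", self.table
        )

    def test_no_content_word_is_error(self):
        with pytest.raises(ValueError):
            phrase_informativeness([TaggedToken("del", "PREP")], self.table)


class TestFinalScore:
    @pytest.mark.parametrize(
        "sim,csim,alpha,expected",
        [(0.8, 0.6, 0.5, 0.7), (0.3, 0.9, 1.0, 0.3), (0.3, 0.9, 0.0, 0.9)],
    )
    def test_convex_combination(self, sim, csim, alpha, expected):
        assert final_score(sim, csim, alpha) == pytest.approx(expected)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            final_score(0.5, 0.5, 1.5)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1), st.floats(0, 1)
    )
    def test_monotone_in_both_arguments(self, a, b, c, alpha):
        lo, hi = sorted((a, b))
        assert final_score(lo, c, alpha) <= final_score(hi, c, alpha) + 1e-12
        assert final_score(c, lo, alpha) <= final_score(c, hi, alpha) + 1e-12


class TestFilterSimpler:
    def _cand(self, text, ci):
        return Candidate(text=text, vector=np.zeros(2), informativeness=ci)

    def test_strict_inequality(self):
        kept = filter_simpler([self._cand("igual", 2.0)], target_ci=2.0)
        assert kept == []

    def test_order_preserved(self):
        cands = [self._cand("x", 1.0), self._cand("y", 0.5), self._cand("z", 3.0)]
        assert [c.text for c in filter_simpler(cands, 2.0)] == ["x", "y"]

    def test_whole_mass_target_removes_everything(self):
        table = FrequencyTable({"todo": 100})
        target_ci = informativeness("todo", table)  # exactly 0
        cands = [self._cand("w", informativeness("w", table))]
        assert filter_simpler(cands, target_ci) == []


class TestMentionTokens:
    def test_function_words_tagged_closed_class(self):
        toks = mention_tokens("dolor de cabeza")
        assert [(t.key, t.tag) for t in toks] == [
            ("dolor", "NN"),
            ("de", "PREP"),
            ("cabeza", "NN"),
        ]

    def test_no_word_tokens_is_error(self):
        with pytest.raises(ValueError):
            mention_tokens("...")
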