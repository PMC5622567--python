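"""Embedding model: word2vec text loading, cosine, phrase vectors, k-NN."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpl_simplify.embeddings import (
    EmbeddingLoadError,
    EmbeddingModel,
    TaggedToken,
    cosine,
    load_embeddings,
    nearest_neighbors,
    phrase_vector,
    save_embeddings,
)

from conftest import brute_cosine


def _write(tmp_path, text, name="vecs.txt"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestLoad:
    def test_header_contract(self, tmp_path):
        path = _write(tmp_path, "3 2\na 1.0 0.0\nb 0.0 1.0\nc 1.0 1.0\n")
        model = load_embeddings(path)
        assert len(model) == 3
        assert model.dimension == 2

    def test_wrong_vector_length_names_line(self, tmp_path):
        path = _write(tmp_path, "3 2\na 1.0 0.0\nb 0.0 1.0 0.5\nc 1.0 1.0\n")
        with pytest.raises(EmbeddingLoadError, match="line 3"):
            load_embeddings(path)

    def test_malformed_header(self, tmp_path):
        with pytest.raises(EmbeddingLoadError, match="line 1"):
            load_embeddings(_write(tmp_path, "2\na 1.0\nb 2.0\n"))

    def test_truncated_file(self, tmp_path):
        with pytest.raises(EmbeddingLoadError, match="line 3"):
            load_embeddings(_write(tmp_path, "2 2\na 1.0 0.0\n"))

    def test_expected_dimension_mismatch(self, tmp_path):
        path = _write(tmp_path, "1 2\na 1.0 0.0\n")
        with pytest.raises(EmbeddingLoadError, match="dimension"):
            load_embeddings(path, expected_dimension=300)

    def test_case_duplicates_keep_first(self, tmp_path, caplog):
        path = _write(tmp_path, "2 2\nA 1.0 0.0\na 0.0 1.0\n")
        with caplog.at_level("WARNING"):
            model = load_embeddings(path)
        assert len(model) == 1
        assert np.allclose(model["a"], [1.0, 0.0])
        assert any("duplicate" in r.message for r in caplog.records)

    def test_accents_preserved_distinct(self, tmp_path):
        path = _write(tmp_path, "2 1\nnáuseas 1.0\nnauseas 2.0\n")
        model = load_embeddings(path)
        assert len(model) == 2
        assert model["náuseas"][0] == 1.0

    def test_roundtrip(self, tmp_path, toy_model):
        path = tmp_path / "out.txt"
        save_embeddings(toy_model, path)
        again = load_embeddings(path, expected_dimension=2)
        assert again.vocabulary() == toy_model.vocabulary()
        for key in again.vocabulary():
            assert np.array_equal(again[key], toy_model[key])


class TestCosine:
    @pytest.mark.parametrize(
        "v1,v2,expected",
        [
            ((1, 0), (1, 0), 1.0),
            ((1, 0), (0, 1), 0.0),
            ((1, 2, 2), (2, 1, 2), 8 / 9),  # dot 8, norms 3 and 3
        ],
    )
    def test_known_values(self, v1, v2, expected):
        assert cosine(np.array(v1, float), np.array(v2, float)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_vector_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert cosine(np.zeros(3), np.ones(3)) == 0.0
        assert any("zero vector" in r.message for r in caplog.records)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=6),
        st.floats(0.01, 100.0),
        st.integers(0, 2**31 - 1),
    )
    def test_symmetry_and_scale_invariance(self, v1, alpha, seed):
        rng = np.random.default_rng(seed)
        v1 = np.asarray(v1)
        v2 = rng.normal(size=v1.size)
        assert cosine(v1, v2) == pytest.approx(cosine(v2, v1), abs=1e-12)
        assert cosine(alpha * v1, v2) == pytest.approx(cosine(v1, v2), abs=1e-12)


class TestPhraseVector:
    def test_single_content_word_bit_identical(self, toy_model):
        vec = phrase_vector(toy_model, [TaggedToken("sueño", "NN")])
        assert np.array_equal(vec, toy_model["sueño"])

    def test_mean_of_content_words(self, toy_model):
        vec = phrase_vector(
            toy_model,
            [TaggedToken("sueño", "NN"), TaggedToken("anormal", "ADJ")],
        )
        assert np.allclose(vec, [1.0, 1.0])

    def test_function_words_do_not_contribute(self, toy_model):
        assert phrase_vector(toy_model, [TaggedToken("del", "PREP")]) is None

    def test_oov_tokens_skipped(self, toy_model):
        vec = phrase_vector(
            toy_model,
            [TaggedToken("sueño", "NN"), TaggedToken("inexistente", "NN")],
        )
        assert np.array_equal(vec, toy_model["sueño"])

    def test_empty_tokens_rejected(self, toy_model):
        with pytest.raises(ValueError):
            phrase_vector(toy_model, [])


class TestNearestNeighbors:
    def test_exhaustive_example(self, toy_model):
        result = nearest_neighbors(
            toy_model, np.array([1.0, 0.0]), k=2, exclude={"a", "sueño", "anormal"}
        )
        assert [w for w, _ in result] == ["c", "b"]
        assert result[0][1] == pytest.approx(2**-0.5)
        assert result[1][1] == pytest.approx(0.0)

    def test_k_exceeding_vocab_returns_all(self, toy_model):
        result = nearest_neighbors(toy_model, np.array([1.0, 0.0]), k=99)
        assert len(result) == len(toy_model)

    def test_tie_broken_lexicographically(self):
        model = EmbeddingModel(
            2, {"zz": np.array([1.0, 0.0]), "aa": np.array([1.0, 0.0])}
        )
        result = nearest_neighbors(model, np.array([1.0, 0.0]), k=2)
        assert [w for w, _ in result] == ["aa", "zz"]

    def test_zero_query_empty(self, toy_model, caplog):
        with caplog.at_level("WARNING"):
            assert nearest_neighbors(toy_model, np.zeros(2), k=3) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n, d = int(rng.integers(5, 100)), int(rng.integers(2, 10))
        vocab = {f"w{i:03d}x": rng.normal(size=d) for i in range(n)}
        model = EmbeddingModel(d, vocab)
        query = rng.normal(size=d)
        expected = sorted(
            ((w, brute_cosine(v, query)) for w, v in vocab.items()),
            key=lambda item: (-item[1], item[0]),
        )[:10]
        got = nearest_neighbors(model, query, k=10)
        assert [w for w, _ in got] == [w for w, _ in expected]
        for (_, sa), (_, sb) in zip(got, expected):
            assert sa == pytest.approx(sb, abs=1e-9)
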