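"""Word extraction, TF-IDF, sentence aggregation and skip-gram training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcpinn.embedding import (
    EmbeddingTable,
    SentenceOfWords,
    TfIdfModel,
    aggregate_sentence,
    compound_to_words,
    fit_tfidf,
    protein_to_words,
    train_word_embeddings,
)


class TestProteinWords:
    def test_shifted_nonoverlapping_ngrams(self):
        sent = protein_to_words("MKVLAG", 3)
        assert sent.words == ["MKV", "LAG", "KVL", "VLA"]
        assert sent.n == 4

    def test_single_word(self):
        assert protein_to_words("MKV", 3).words == ["MKV"]

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter than word size"):
            protein_to_words("MK", 3)

    @given(st.text(alphabet="ACDEFGHIK", min_size=3, max_size=60),
           st.integers(min_value=1, max_value=3))
    @settings(max_examples=100, deadline=None)
    def test_word_count_formula(self, seq, n):
        sent = protein_to_words(seq, n)
        expected = sum((len(seq) - shift) // n for shift in range(n))
        assert sent.n == expected
        # every word is a length-n window of the sequence
        windows = {seq[i : i + n] for i in range(len(seq) - n + 1)}
        assert set(sent.words) <= windows


class TestCompoundWords:
    def test_single_atom(self):
        assert compound_to_words("C", {0}).n == 1

    def test_symmetric_atoms_give_equal_words(self):
        sent = compound_to_words("CC", {0})
        assert sent.n == 2
        assert sent.words[0] == sent.words[1]

    def test_counts_and_identifiers_match_fingerprint_bit_info(self):
        # independent enumeration through the raw bit-info map
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        sent = compound_to_words("CCO", {0, 1})
        assert sent.n == 6  # 3 heavy atoms x 2 radii
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=1)
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        gen.GetSparseCountFingerprint(Chem.MolFromSmiles("CCO"), additionalOutput=ao)
        oracle = {str(bit) for bit in ao.GetBitInfoMap()}
        assert set(sent.words) == oracle

    def test_unparseable_smiles_raises_with_input(self):
        with pytest.raises(ValueError, match="not-a-smiles"):
            compound_to_words("not-a-smiles", {0})


class TestTfIdf:
    def test_single_document_idf_is_one(self):
        model = fit_tfidf([SentenceOfWords(["a", "b"])])
        assert model.idf("a") == pytest.approx(1.0)

    def test_smoothed_idf_formula(self):
        docs = [SentenceOfWords(w) for w in (["a", "b"], ["b"], ["b", "c"])]
        model = fit_tfidf(docs)
        assert model.idf("a") == pytest.approx(math.log(4 / 2) + 1, abs=1e-4)
        assert model.idf("zzz") == pytest.approx(math.log(4 / 1) + 1, abs=1e-4)

    def test_agrees_with_sklearn_smooth_idf(self):
        from sklearn.feature_extraction.text import TfidfVectorizer

        docs = [["a", "b", "b"], ["b", "c"], ["c", "c", "d"], ["a"]]
        model = fit_tfidf([SentenceOfWords(d) for d in docs])
        vec = TfidfVectorizer(analyzer=lambda d: d, norm=None, smooth_idf=True)
        vec.fit(docs)
        for word, idx in vec.vocabulary_.items():
            assert model.idf(word) == pytest.approx(vec.idf_[idx], abs=1e-12)

    def test_idf_monotone_in_document_frequency(self, rng):
        words = [f"w{i}" for i in range(30)]
        docs = [SentenceOfWords(list(rng.choice(words, size=5))) for _ in range(40)]
        model = fit_tfidf(docs)
        pairs = sorted(model.document_frequency.items(), key=lambda kv: kv[1])
        idfs = [model.idf(w) for w, _ in pairs]
        assert all(a >= b - 1e-12 for a, b in zip(idfs, idfs[1:]))

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError, match="empty corpus"):
            fit_tfidf([])

    def test_serialization_roundtrip(self, tmp_path):
        model = fit_tfidf([SentenceOfWords(["a", "b"]), SentenceOfWords(["b"])])
        path = tmp_path / "tfidf.tsv"
        model.save(path)
        loaded = TfIdfModel.load(path)
        assert loaded.n_documents == model.n_documents
        assert loaded.document_frequency == model.document_frequency


def _table(vectors: dict[str, list[float]]) -> EmbeddingTable:
    return EmbeddingTable(dimension=len(next(iter(vectors.values()))),
                          vectors={k: np.array(v, dtype=float) for k, v in vectors.items()})


class TestAggregation:
    def test_two_vector_hand_computation(self):
        table = _table({"x": [1.0, 0.0], "y": [0.0, 1.0]})
        sent = SentenceOfWords(["x", "y"])
        assert aggregate_sentence(sent, table, "sum").tolist() == [1.0, 1.0]
        assert aggregate_sentence(sent, table, "mean").tolist() == [0.5, 0.5]

    def test_single_word_identity_under_all_schemes(self):
        table = _table({"v": [2.0, -1.0]})
        sent = SentenceOfWords(["v"])
        tfidf = fit_tfidf([sent])  # idf = 1 for the only word
        for scheme in ("sum", "mean", "tfidf"):
            out = aggregate_sentence(sent, table, scheme, tfidf)
            assert out.tolist() == [2.0, -1.0]

    def test_tfidf_with_unit_weights_equals_sum(self):
        table = _table({"a": [1.0, 2.0], "b": [3.0, -1.0]})
        sent = SentenceOfWords(["a", "b", "a"])
        tfidf = fit_tfidf([sent])  # every word in the single document: idf 1
        np.testing.assert_allclose(
            aggregate_sentence(sent, table, "tfidf", tfidf),
            aggregate_sentence(sent, table, "sum"))

    def test_oov_policy(self):
        table = _table({"a": [1.0]})
        out = aggregate_sentence(SentenceOfWords(["a", "missing"]), table, "sum")
        assert out.tolist() == [1.0]
        table.oov_policy = "error"
        with pytest.raises(KeyError):
            aggregate_sentence(SentenceOfWords(["missing"]), table, "sum")

    def test_empty_sentence_raises(self):
        with pytest.raises(ValueError):
            aggregate_sentence(SentenceOfWords([]), _table({"a": [1.0]}), "sum")

    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=8),
           st.integers(min_value=2, max_value=4))
    @settings(max_examples=100, deadline=None)
    def test_sum_mean_linearity_and_duplication(self, words, k):
        rng = np.random.default_rng(1)
        table = _table({w: rng.standard_normal(3).tolist() for w in "abc"})
        sent = SentenceOfWords(list(words))
        dup = SentenceOfWords(list(words) * k)
        s, m = aggregate_sentence(sent, table, "sum"), aggregate_sentence(sent, table, "mean")
        np.testing.assert_allclose(s, sent.n * m, atol=1e-9)
        np.testing.assert_allclose(aggregate_sentence(dup, table, "mean"), m, atol=1e-9)
        np.testing.assert_allclose(aggregate_sentence(dup, table, "sum"), k * s, atol=1e-9)


class TestSkipGram:
    CORPUS = [SentenceOfWords(list(w)) for w in
              ["abcabc", "bcabca", "cababc", "abacbc", "qabc"]]

    def test_min_count_drops_rare_words(self):
        table = train_word_embeddings(self.CORPUS, d=8, window=3, min_count=2, seed=0, epochs=1)
        assert "q" not in table
        assert np.all(table.lookup("q") == 0.0)  # zero policy
        assert set(table.vectors) == {"a", "b", "c"}

    def test_dimension_contract_and_determinism(self):
        t1 = train_word_embeddings(self.CORPUS, d=8, window=3, min_count=1, seed=3, epochs=2)
        t2 = train_word_embeddings(self.CORPUS, d=8, window=3, min_count=1, seed=3, epochs=2)
        assert all(v.shape == (8,) for v in t1.vectors.values())
        for w in t1.vectors:
            np.testing.assert_array_equal(t1.vectors[w], t2.vectors[w])

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            train_word_embeddings(self.CORPUS, d=0, window=3, min_count=1, seed=0)
        with pytest.raises(ValueError):
            train_word_embeddings(self.CORPUS, d=4, window=0, min_count=1, seed=0)

    def test_word2vec_text_roundtrip(self, tmp_path):
        table = train_word_embeddings(self.CORPUS, d=4, window=2, min_count=1, seed=0, epochs=1)
        path = tmp_path / "emb.txt"
        table.save(path)
        loaded = EmbeddingTable.load(path)
        assert loaded.dimension == 4
        for w, v in table.vectors.items():
            np.testing.assert_allclose(loaded.vectors[w], v)
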