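"""VSM cosine, Lin taxonomy similarity, embeddings, alignment, combination
and the Pearson evaluation harness."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import curatext as ct
from curatext.similarity import SimilarityConfig, _content_words


class TestVectorize:
    def test_worked_example_stemmed_counts(self):
        v = ct.vectorize("Activated OxyR then induces transcription")
        assert v == {"activ": 1, "oxyr": 1, "then": 1, "induc": 1, "transcript": 1}

    def test_empty_sentence_gives_empty_vector(self):
        assert ct.vectorize("") == {}
        assert ct.vectorize("123 456 ...") == {}  # no alphabetic tokens

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(8)
        vocab = ["gene", "genes", "activation", "activates", "OxyR", "the", "cell"]
        for _ in range(100):
            words = [vocab[i] for i in rng.integers(0, len(vocab), size=rng.integers(1, 20))]
            text = " ".join(words)
            expected: dict[str, int] = {}
            for w in words:
                expected[ct.stem(w)] = expected.get(ct.stem(w), 0) + 1
            assert ct.vectorize(text) == expected

    def test_stopword_removal_and_stemming_toggles(self):
        cfg = SimilarityConfig(stemming=False, stopwords=frozenset({"the"}))
        assert ct.vectorize("The genes", cfg) == {"genes": 1}
        assert ct.vectorize("The genes") == {"the": 1, "gene": 1}


class TestCosine:
    def test_identical_nonempty_vectors_score_one(self):
        v = {"a": 2, "b": 1}
        assert ct.cosine(v, v) == pytest.approx(1.0)

    def test_disjoint_vectors_score_zero(self):
        assert ct.cosine({"a": 1}, {"b": 3}) == 0.0

    def test_hand_computed_half(self):
        assert ct.cosine({"a": 1, "b": 1}, {"a": 1, "c": 1}) == pytest.approx(0.5)

    def test_empty_vector_defined_as_zero(self):
        assert ct.cosine({}, {"a": 1}) == 0.0

    def test_matches_dense_dot_product_oracle(self):
        rng = np.random.default_rng(21)
        keys = [f"k{i}" for i in range(12)]
        for _ in range(1000):
            v1 = {k: int(c) for k, c in zip(keys, rng.integers(0, 4, len(keys))) if c}
            v2 = {k: int(c) for k, c in zip(keys, rng.integers(0, 4, len(keys))) if c}
            a = np.array([v1.get(k, 0) for k in keys], float)
            b = np.array([v2.get(k, 0) for k in keys], float)
            if not v1 or not v2:
                expected = 0.0
            else:
                expected = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
            got = ct.cosine(v1, v2)
            assert got == pytest.approx(expected)
            assert got == pytest.approx(ct.cosine(v2, v1))
            assert -1e-12 <= got <= 1 + 1e-12


@pytest.fixture(scope="module")
def toy_taxonomy():
    """root -> (Z, W); Z -> (X, Y); cumulative p(X)=p(Y)=1/4, p(Z)=1/2."""
    return ct.Taxonomy(
        parents={"root": [], "Z": ["root"], "W": ["root"], "X": ["Z"], "Y": ["Z"]},
        frequencies={"root": 0.0, "Z": 0.0, "W": 4.0, "X": 2.0, "Y": 2.0},
        word_map={"wx": ["X"], "wy": ["Y"], "wz": ["Z"], "ww": ["W"]},
    )


class TestLinSimilarity:
    def test_ic_root_is_zero_and_nondecreasing(self, toy_taxonomy):
        t = toy_taxonomy
        assert t.ic["root"] == 0.0
        assert t.ic["Z"] == pytest.approx(math.log(2))
        assert t.ic["X"] == pytest.approx(math.log(4))
        assert t.ic["X"] >= t.ic["Z"] >= t.ic["root"]

    def test_sibling_fixture_scores_half(self, toy_taxonomy):
        # 2 * IC(Z) / (IC(X) + IC(Y)) = 2 log 2 / (2 log 4) = 0.5
        assert ct.lin_similarity(toy_taxonomy, "wx", "wy") == pytest.approx(0.5)

    def test_self_similarity_of_non_root_concept_is_one(self, toy_taxonomy):
        assert ct.lin_similarity(toy_taxonomy, "wx", "wx") == pytest.approx(1.0)

    def test_lcs_at_root_scores_zero(self, toy_taxonomy):
        assert ct.lin_similarity(toy_taxonomy, "wx", "ww") == 0.0

    def test_out_of_vocabulary_scores_zero(self, toy_taxonomy):
        assert ct.lin_similarity(toy_taxonomy, "wx", "nope") == 0.0
        assert not toy_taxonomy.contains_word("nope")

    def test_monotone_in_subsumer_information_content(self):
        # keep IC(c1), IC(c2) fixed (cumulative 1 of total 16) while the
        # subsumer S grows rarer: score 2 IC(S) / (IC(c1) + IC(c2)) rises
        scores = []
        for s_own in (14.0, 6.0, 2.0):
            tax = ct.Taxonomy(
                parents={"root": [], "S": ["root"], "O": ["root"],
                         "c1": ["S"], "c2": ["S"]},
                frequencies={"root": 0.0, "S": s_own, "O": 14.0 - s_own,
                             "c1": 1.0, "c2": 1.0},
                word_map={"w1": ["c1"], "w2": ["c2"]},
            )
            assert tax._cumulative["root"] == pytest.approx(16.0)
            assert tax.ic["c1"] == pytest.approx(math.log(16))
            scores.append(ct.lin_similarity(tax, "w1", "w2"))
        assert scores[0] < scores[1] < scores[2]
        assert scores == pytest.approx([0.0, 0.25, 0.5])

    def test_ambiguous_words_take_max_over_senses(self, toy_taxonomy):
        tax = ct.Taxonomy(
            parents=toy_taxonomy.parents,
            frequencies=toy_taxonomy.frequencies,
            word_map={"amb": ["X", "W"], "wy": ["Y"]},
        )
        # sense X gives 0.5 via Z; sense W gives 0 via root -> max is 0.5
        assert ct.lin_similarity(tax, "amb", "wy") == pytest.approx(0.5)

    def test_taxonomy_tsv_round_trip(self, toy_taxonomy, tmp_path):
        cp, wp = tmp_path / "tax.tsv", tmp_path / "words.tsv"
        toy_taxonomy.write(cp, wp)
        back = ct.Taxonomy.from_files(cp, wp)
        assert back.ic == pytest.approx(toy_taxonomy.ic)
        assert back.word_map == toy_taxonomy.word_map


class TestEmbeddings:
    def test_self_similarity_one_orthogonal_zero_antipodal_clamped(self):
        wv = ct.WordVectors({"a": [1, 0], "b": [0, 1], "c": [-1, 0]})
        assert ct.embedding_word_sim(wv, "a", "a") == pytest.approx(1.0)
        assert ct.embedding_word_sim(wv, "a", "b") == 0.0
        assert ct.embedding_word_sim(wv, "a", "c") == 0.0  # clamp of -1

    def test_out_of_vocabulary_scores_zero(self):
        wv = ct.WordVectors({"a": [1.0, 0.0]})
        assert ct.embedding_word_sim(wv, "a", "zz") == 0.0

    def test_dimension_mismatch_in_file_is_load_error(self, tmp_path):
        p = tmp_path / "vec.txt"
        p.write_text("2 3\naaa 1 0 0\nbbb 1 0\n", encoding="utf-8")
        with pytest.raises(ValueError, match="bbb"):
            ct.WordVectors.from_file(p)

    def test_text_format_round_trip(self, tmp_path):
        wv = ct.WordVectors({"alpha": [0.5, -1.25, 3.0], "beta": [1, 2, 3]})
        p = tmp_path / "v.txt"
        wv.write(p)
        back = ct.WordVectors.from_file(p)
        assert back.dim == 3
        np.testing.assert_allclose(back.vectors["alpha"], wv.vectors["alpha"])


class TestAlignedWordScore:
    def test_identical_sentences_score_one(self):
        sim = lambda a, b: 1.0 if a == b else 0.0
        assert ct.aligned_word_score(["x", "y"], ["x", "y"], sim) == 1.0

    def test_no_similar_pair_scores_zero(self):
        assert ct.aligned_word_score(["a"], ["b"], lambda a, b: 0.0) == 0.0

    def test_empty_side_scores_zero(self):
        assert ct.aligned_word_score([], ["a"], lambda a, b: 1.0) == 0.0

    def test_hand_computed_two_by_two(self):
        table = {("a", "c"): 0.8, ("a", "d"): 0.1, ("b", "c"): 0.2, ("b", "d"): 0.4}
        sim = lambda x, y: table.get((x, y), table.get((y, x), 0.0))
        # best matches in both directions: a->c 0.8, b->d 0.4; c->a 0.8, d->b 0.4
        assert ct.aligned_word_score(["a", "b"], ["c", "d"], sim) == pytest.approx(0.6)


class TestCombinedSimilarity:
    def test_identical_sentences_scale_to_five(self, toy_taxonomy):
        wv = ct.WordVectors({"wx": [1.0, 0.0], "wy": [0.0, 1.0]})
        cfg = SimilarityConfig(weight_vsm=1, weight_taxonomy=1, weight_embedding=1,
                               taxonomy=toy_taxonomy, vectors=wv)
        s = ct.combined_similarity("wx wy wx", "wx wy wx", cfg)
        assert s.scaled == pytest.approx(5.0)

    def test_vsm_only_weights_reduce_to_cosine(self):
        s1, s2 = "OxyR activates katG", "OxyR represses oxyS"
        score = ct.combined_similarity(s1, s2)
        expected = ct.cosine(ct.vectorize(s1), ct.vectorize(s2))
        assert score.scaled == pytest.approx(5.0 * expected)
        assert score.metrics == {"cosine_vsm": pytest.approx(expected)}

    def test_on_topic_pair_beats_distractor(self):
        from conftest import SENT_A, SENT_B, DISTRACTORS
        ab = ct.combined_similarity(SENT_A, SENT_B).scaled
        off = ct.combined_similarity(SENT_A, DISTRACTORS[0]).scaled
        assert ab > off

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            SimilarityConfig(weight_vsm=0.0)

    def test_stemming_collapses_inflection(self):
        s1, s2 = "X activates Y", "activation of Y by X"
        with_stem = ct.combined_similarity(s1, s2, SimilarityConfig(stemming=True)).scaled
        without = ct.combined_similarity(s1, s2, SimilarityConfig(stemming=False)).scaled
        assert with_stem > without

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        vocab = ["oxyr", "katg", "gene", "activ", "cell", "stress", "medium"]
        t1 = " ".join(vocab[i] for i in rng.integers(0, len(vocab), rng.integers(0, 8)))
        t2 = " ".join(vocab[i] for i in rng.integers(0, len(vocab), rng.integers(0, 8)))
        a, b = ct.combined_similarity(t1, t2), ct.combined_similarity(t2, t1)
        assert a.scaled == pytest.approx(b.scaled)
        assert 0.0 <= a.combined <= 1.0
        assert 0.0 <= a.scaled <= 5.0


class TestPearson:
    def test_perfect_linear_relation(self):
        xs = [1.0, 2.0, 3.0, 4.0]
        assert ct.pearson(xs, [2 * x + 1 for x in xs]) == pytest.approx(1.0)

    def test_perfect_inverse_relation(self):
        xs = [1.0, 2.0, 3.0]
        assert ct.pearson(xs, [-x for x in xs]) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        assert ct.pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            ct.pearson([1, 1, 1], [1, 2, 3])


class TestEvaluateSts:
    def test_self_scored_gold_gives_r_one(self):
        spec = ct.FixtureSpec(seed=11, noise_sigma=0.0)
        scorer = lambda a, b: ct.combined_similarity(a, b).scaled
        pairs = ct.gen_gold_pairs(spec, scorer, n_pairs=50)
        report = ct.evaluate_sts(pairs)
        assert report.pearson_r == pytest.approx(1.0)

    def test_inverted_gold_gives_r_minus_one(self):
        scorer = lambda a, b: ct.combined_similarity(a, b).scaled
        spec = ct.FixtureSpec(seed=11, noise_sigma=0.0)
        pairs = [ct.GoldPair(p.text1, p.text2, 5.0 - p.gold)
                 for p in ct.gen_gold_pairs(spec, scorer, n_pairs=50)]
        assert ct.evaluate_sts(pairs).pearson_r == pytest.approx(-1.0)

    def test_noisy_gold_keeps_high_correlation(self):
        spec = ct.FixtureSpec(seed=11, noise_sigma=0.3)
        scorer = lambda a, b: ct.combined_similarity(a, b).scaled
        pairs = ct.gen_gold_pairs(spec, scorer, n_pairs=200)
        assert ct.evaluate_sts(pairs).pearson_r >= 0.9

    def test_per_pair_tsv_written(self, tmp_path):
        pairs = [ct.GoldPair("a b", "a b", 5.0), ct.GoldPair("a b", "c d", 0.0),
                 ct.GoldPair("a c", "a d", 2.0)]
        report = ct.evaluate_sts(pairs)
        out = tmp_path / "scores.tsv"
        report.write_tsv(out)
        import pandas as pd
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == ["system", "gold"] and len(df) == 3
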