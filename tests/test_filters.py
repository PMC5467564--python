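"""Filter grammar, boolean semantics and corpus selection."""

import numpy as np
import pytest

import curatext as ct
from curatext.filters import And, Atom, Not, Or, FilterSyntaxError, eval_filter


@pytest.fixture(scope="module")
def effect_lex():
    return {"effect": ct.Lexicon("effect", frozenset({ct.stem(w) for w in (
        "activates", "activation", "repress", "repression", "regulated",
        "regulate", "upregulates", "induces")}), match_on="stem")}


class TestParseFilter:
    def test_and_of_two_atoms(self):
        e = ct.parse_filter("type:TF AND lexicon:effect")
        assert e == And(Atom("type", "TF"), Atom("lexicon", "effect"))

    def test_not_binds_tighter_than_and(self):
        e = ct.parse_filter("NOT type:TF AND type:GENE")
        assert e == And(Not(Atom("type", "TF")), Atom("type", "GENE"))

    def test_and_binds_tighter_than_or(self):
        e = ct.parse_filter("type:TF OR type:GENE AND lexicon:effect")
        assert e == Or(Atom("type", "TF"), And(Atom("type", "GENE"), Atom("lexicon", "effect")))

    def test_parens_override_precedence(self):
        e = ct.parse_filter("(type:TF OR type:GENE) AND lexicon:effect")
        assert e == And(Or(Atom("type", "TF"), Atom("type", "GENE")), Atom("lexicon", "effect"))

    def test_keywords_case_insensitive(self):
        assert ct.parse_filter("type:TF and not type:GENE") == And(
            Atom("type", "TF"), Not(Atom("type", "GENE")))

    def test_term_atom_with_quoted_payload(self):
        assert ct.parse_filter('term:"heat shock"') == Atom("term", "heat shock")

    def test_syntax_error_reports_position(self):
        with pytest.raises(FilterSyntaxError) as exc:
            ct.parse_filter("type:TF AND (type:GENE OR")
        assert exc.value.position == 12  # the unbalanced "("

    def test_unknown_lexicon_rejected_when_registry_given(self, effect_lex):
        with pytest.raises(FilterSyntaxError, match="ghost"):
            ct.parse_filter("lexicon:ghost", lexicons=effect_lex)

    def test_round_trip_through_canonical_printer(self):
        exprs = [
            "type:TF AND lexicon:effect",
            "NOT (type:TF OR type:GENE)",
            "type:TF OR NOT type:GENE AND lexicon:effect",
            'term:"oxyS promoter" AND NOT type:TU',
        ]
        for src in exprs:
            e = ct.parse_filter(src)
            assert ct.parse_filter(e.to_string()) == e


class TestEvalFilter:
    def test_worked_example_tf_and_effect(self, example_doc, example_mentions, effect_lex):
        e = ct.parse_filter("type:TF AND lexicon:effect", lexicons=effect_lex)
        sent = example_doc.sentences[0]
        assert eval_filter(e, sent, example_mentions, effect_lex, example_doc.sentence_text(sent))

    def test_not_type_true_without_mentions(self, effect_lex):
        doc = ct.preprocess(ct.Document("d", "plain sentence."))
        e = ct.parse_filter("NOT type:TF")
        assert eval_filter(e, doc.sentences[0], [], effect_lex, doc.text)

    def test_lexicon_atom_matches_on_stems(self, effect_lex):
        doc = ct.preprocess(ct.Document("d", "Strong activation was observed."))
        e = ct.parse_filter("lexicon:effect", lexicons=effect_lex)
        assert eval_filter(e, doc.sentences[0], [], effect_lex, doc.text)


def random_expr(rng, atoms, depth=0):
    roll = rng.random()
    if depth >= 3 or roll < 0.35:
        return atoms[rng.integers(len(atoms))]
    if roll < 0.55:
        return Not(random_expr(rng, atoms, depth + 1))
    cls = And if roll < 0.8 else Or
    return cls(random_expr(rng, atoms, depth + 1), random_expr(rng, atoms, depth + 1))


def truth_table_oracle(expr, atom_truth):
    """Independent evaluation: resolve atoms to booleans, then fold with
    plain Python logic."""
    if isinstance(expr, Atom):
        return atom_truth[expr]
    if isinstance(expr, Not):
        return not truth_table_oracle(expr.operand, atom_truth)
    if isinstance(expr, And):
        return truth_table_oracle(expr.left, atom_truth) and truth_table_oracle(expr.right, atom_truth)
    return truth_table_oracle(expr.left, atom_truth) or truth_table_oracle(expr.right, atom_truth)


def _random_annotated_sentence(rng, effect_lex):
    words = ["activation", "binding", "growth", "oxyS", "medium", "regulated", "level"]
    chosen = [words[i] for i in rng.integers(0, len(words), size=rng.integers(1, 7))]
    doc = ct.preprocess(ct.Document("d", " ".join(chosen) + "."))
    sent = doc.sentences[0]
    mentions = []
    for etype in ("TF", "GENE", "TU"):
        if rng.random() < 0.5:
            tok = sent.tokens[0]
            mentions.append(ct.EntityMention(
                "d", sent.sent_id, 0, 1, tok.char_start, tok.char_end,
                tok.surface, [f"E:{etype}"], etype))
    return doc, sent, mentions


class TestFilterOracle:
    def test_500_random_cases_match_truth_table(self, effect_lex):
        rng = np.random.default_rng(77)
        atoms = [Atom("type", "TF"), Atom("type", "GENE"), Atom("type", "TU"),
                 Atom("lexicon", "effect"), Atom("term", "oxyS")]
        for _ in range(500):
            doc, sent, mentions = _random_annotated_sentence(rng, effect_lex)
            expr = random_expr(rng, atoms)
            text = doc.sentence_text(sent)
            atom_truth = {a: eval_filter(a, sent, mentions, effect_lex, text) for a in atoms}
            assert eval_filter(expr, sent, mentions, effect_lex, text) == \
                truth_table_oracle(expr, atom_truth)


@pytest.fixture(scope="module")
def annotated_corpus(effect_lex):
    gen = ct.gen_corpus(ct.FixtureSpec(seed=3, n_docs=6))
    matcher = ct.compile_dictionary(gen.dictionary)
    annotations = ct.annotate_corpus(gen.corpus, matcher)
    return gen.corpus, annotations


class TestSelectSentences:
    def test_nothing_matches_empty_selection_fraction_zero(self, annotated_corpus, effect_lex):
        corpus, ann = annotated_corpus
        sel, frac = ct.select_sentences(corpus, ct.parse_filter("type:PROMOTER"), ann, effect_lex)
        assert sel == [] and frac == 0.0

    def test_tautology_selects_everything(self, annotated_corpus, effect_lex):
        corpus, ann = annotated_corpus
        sel, frac = ct.select_sentences(
            corpus, ct.parse_filter("type:TF OR NOT type:TF"), ann, effect_lex)
        assert frac == 1.0
        assert len(sel) == sum(len(d.sentences) for d in corpus)

    def test_planted_tf_effect_sentences_recovered_exactly(self):
        from curatext.synthetic_fixtures import default_effect_lexicon
        gen = ct.gen_corpus(ct.FixtureSpec(seed=9, n_docs=5))
        lex = {"effect": ct.Lexicon("effect", frozenset(default_effect_lexicon()))}
        matcher = ct.compile_dictionary(gen.dictionary)
        ann = ct.annotate_corpus(gen.corpus, matcher)
        expr = ct.parse_filter("type:TF AND lexicon:effect", lexicons=lex)
        sel, _ = ct.select_sentences(gen.corpus, expr, ann, lex)
        planted = [(m.doc_id, m.sent_id) for doc in gen.corpus
                   for m in gen.planted_mentions[doc.doc_id] if m.entity_type == "TF"]
        assert sel == sorted(set(planted), key=lambda k: planted.index(k))

    def test_de_morgan_equivalence_corpus_wide(self, annotated_corpus, effect_lex):
        corpus, ann = annotated_corpus
        e1 = ct.parse_filter("NOT (type:TF AND lexicon:effect)")
        e2 = ct.parse_filter("NOT type:TF OR NOT lexicon:effect")
        s1, _ = ct.select_sentences(corpus, e1, ann, effect_lex)
        s2, _ = ct.select_sentences(corpus, e2, ann, effect_lex)
        assert s1 == s2

    def test_and_selection_is_intersection(self, annotated_corpus, effect_lex):
        corpus, ann = annotated_corpus
        a, _ = ct.select_sentences(corpus, ct.parse_filter("type:TF"), ann, effect_lex)
        b, _ = ct.select_sentences(corpus, ct.parse_filter("lexicon:effect"), ann, effect_lex)
        both, _ = ct.select_sentences(
            corpus, ct.parse_filter("type:TF AND lexicon:effect"), ann, effect_lex)
        assert set(both) == set(a) & set(b)

    def test_fraction_non_increasing_with_extra_conjuncts(self, annotated_corpus, effect_lex):
        corpus, ann = annotated_corpus
        fracs = []
        for expr in ("type:TF", "type:TF AND lexicon:effect",
                     "type:TF AND lexicon:effect AND type:GENE",
                     "type:TF AND lexicon:effect AND type:GENE AND term:\"zzz\""):
            _, f = ct.select_sentences(corpus, ct.parse_filter(expr), ann, effect_lex)
            fracs.append(f)
        assert fracs == sorted(fracs, reverse=True)
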