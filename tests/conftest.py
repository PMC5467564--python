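"""Shared fixtures: the worked-example sentence with its dependency parse,
the oxidative-stress linking corpus, and a hand-checkable disambiguation toy."""

from __future__ import annotations

import pytest
from hypothesis import settings

import curatext as ct

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


EXAMPLE_TEXT = (
    "Activated OxyR then induces transcription of antioxidant genes, "
    "including katG, ahpCF, and oxyS"
)

# 1-based CoNLL-U heads for the 16 tokens of EXAMPLE_TEXT: the interaction verb
# "induces" is the root; OxyR hangs off it as subject and the gene conjuncts
# reach it through "genes" -> "transcription".
EXAMPLE_CONLLU = """\
# sent_id = exdoc.s0
1\tActivated\t_\t_\t_\t_\t2\tamod\t_\t_
2\tOxyR\t_\t_\t_\t_\t4\tnsubj\t_\t_
3\tthen\t_\t_\t_\t_\t4\tadvmod\t_\t_
4\tinduces\t_\t_\t_\t_\t0\troot\t_\t_
5\ttranscription\t_\t_\t_\t_\t4\tobj\t_\t_
6\tof\t_\t_\t_\t_\t8\tcase\t_\t_
7\tantioxidant\t_\t_\t_\t_\t8\tamod\t_\t_
8\tgenes\t_\t_\t_\t_\t5\tnmod\t_\t_
9\t,\t_\t_\t_\t_\t11\tpunct\t_\t_
10\tincluding\t_\t_\t_\t_\t11\tcase\t_\t_
11\tkatG\t_\t_\t_\t_\t8\tnmod\t_\t_
12\t,\t_\t_\t_\t_\t13\tpunct\t_\t_
13\tahpCF\t_\t_\t_\t_\t11\tconj\t_\t_
14\t,\t_\t_\t_\t_\t16\tpunct\t_\t_
15\tand\t_\t_\t_\t_\t16\tcc\t_\t_
16\toxyS\t_\t_\t_\t_\t11\tconj\t_\t_
"""

EXAMPLE_DICT = [
    ct.TermEntry("OxyR", "RDB:OXYR", "TF", "regdb"),
    ct.TermEntry("katG", "RDB:KATG", "GENE", "regdb"),
    ct.TermEntry("ahpCF", "RDB:AHPCF", "GENE", "regdb"),
    ct.TermEntry("oxyS", "RDB:OXYS", "GENE", "regdb"),
]

EFFECT_WORDS = [
    "activates", "activation", "repress", "repression", "regulated",
    "regulate", "upregulates", "induces", "induction",
]


@pytest.fixture(scope="session")
def example_doc() -> ct.Document:
    doc = ct.Document("exdoc", EXAMPLE_TEXT)
    ct.preprocess(doc)
    return doc


@pytest.fixture(scope="session")
def example_matcher() -> ct.Matcher:
    return ct.compile_dictionary(EXAMPLE_DICT)


@pytest.fixture(scope="session")
def example_mentions(example_doc, example_matcher):
    return ct.annotate(example_doc, example_matcher)


@pytest.fixture(scope="session")
def example_tree(tmp_path_factory, example_doc):
    path = tmp_path_factory.mktemp("conllu") / "example.conllu"
    path.write_text(EXAMPLE_CONLLU, encoding="utf-8")
    expected = {s.sent_id: len(s.tokens) for s in example_doc.sentences}
    return ct.read_conllu(path, expected_tokens=expected)["exdoc.s0"]


@pytest.fixture(scope="session")
def effect_lexicon() -> dict[str, str]:
    polarity = {"repress": "repression", "repression": "repression"}
    return {ct.stem(w): polarity.get(w, "activation") for w in EFFECT_WORDS}


# --- the oxidative-stress linking corpus -----------------------------------

SENT_A = (
    "The oxidized form of OxyR is a transcriptional activator of a multitude "
    "of genes that assist in protecting the cell from oxidative damage."
)
SENT_B = (
    "Activated OxyR then induces transcription of a set of antioxidant genes, "
    "including katG (hydroperoxidase I), ahpCF (alkylhydroperoxidase), dps (a "
    "non-specific DNA binding protein), gorA (glutathione reductase), grxA "
    "(glutaredoxin I) and oxyS (a regulatory RNA)."
)
SENT_C = (
    "A hallmark of the E. coli response to hydrogen peroxide is the rapid and "
    "strong induction of a set of OxyR-regulated genes, including dps, katG, "
    "grxA, ahpCF and trxC."
)
DISTRACTORS = [
    "The committee postponed its quarterly budget meeting until early spring.",
    "Fresh snow covered the mountain trails before the hikers arrived.",
    "Her violin concerto received warm applause from the packed concert hall.",
    "The chef simmered the tomato sauce slowly over a low flame.",
    "Commuter trains were delayed after signal failures near the central station.",
]


@pytest.fixture(scope="session")
def linking_corpus() -> list[ct.Document]:
    """a, b, c in their own documents plus five one-sentence distractor docs."""
    texts = {"artA": SENT_A, "artB": SENT_B, "artC": SENT_C}
    texts.update({f"off{i}": d for i, d in enumerate(DISTRACTORS)})
    return [ct.preprocess(ct.Document(doc_id, text)) for doc_id, text in texts.items()]


def topical_threshold(corpus: list[ct.Document]) -> float:
    """Fixture-derived threshold: midpoint between the weakest on-topic pair
    and the strongest remaining pair under the VSM-only config."""
    on_topic_ids = {"artA", "artB", "artC"}
    items = [(d.doc_id, d.sentence_text(d.sentences[0])) for d in corpus]
    topic, rest = [], []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            s = ct.combined_similarity(items[i][1], items[j][1]).scaled
            bucket = topic if {items[i][0], items[j][0]} <= on_topic_ids else rest
            bucket.append(s)
    return (min(topic) + max(rest)) / 2.0


# --- hand-checkable distant-supervision toy --------------------------------

@pytest.fixture(scope="session")
def nb_toy():
    """Two training documents with the ambiguous surface "FurX".

    Counts are tiny enough to verify the smoothed naive-Bayes posterior by
    hand (see test_disambiguation for the arithmetic).
    """
    corpus = [
        ct.preprocess(ct.Document("t1", "alpha beta FurX gamma.")),
        ct.preprocess(ct.Document("t2", "delta epsilon FurX zeta.")),
    ]
    entries = [
        ct.TermEntry("FurX", "E:A", "TF", "synthetic"),
        ct.TermEntry("FurX", "E:B", "GENE", "synthetic"),
    ]
    matcher = ct.compile_dictionary(entries)
    links = [ct.ReferenceLink("t1", "E:A"), ct.ReferenceLink("t2", "E:B")]
    model = ct.train_distant(corpus, links, matcher, alpha=1.0)
    return {"corpus": corpus, "matcher": matcher, "links": links, "model": model}
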