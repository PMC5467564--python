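"""Seeded synthetic generators for every input the pipeline consumes.

Real runs consume article text, terminology TSVs, database links, CoNLL-U
parses, taxonomies and word-vector files. The generators here emulate all
of those offline with planted ground truth, so every module is testable
end-to-end with no downloads. Sentences are template-generated ("<TF>
<effect-verb> transcription of <gene> ...") from per-topic word
distributions — only the statistical and lexical structure matters to the
consumers, not grammaticality.

All generators are driven by a :class:`FixtureSpec`; the same spec yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core_text import Document, preprocess
from .disambiguation import ReferenceLink
from .similarity import GoldPair, Taxonomy, WordVectors
from .terminology import EntityMention, TermEntry

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the fixture generators; same spec => identical output."""

    seed: int = 0
    n_docs: int = 10
    sentences_per_doc: int = 6
    topic_vocab_size: int = 30
    shared_vocab_size: int = 10
    n_tfs: int = 4
    n_genes: int = 8
    ambiguity_rate: float = 0.2
    plain_sentence_rate: float = 0.25
    n_topics: int = 3
    heldout_docs: int = 10
    noise_sigma: float = 0.3
    embedding_dim: int = 50

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _word(rng: np.random.Generator, syllables: int = 2) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(syllables)
    )


def _vocab(rng: np.random.Generator, n: int, syllables: int = 2) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        w = _word(rng, syllables)
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


_EFFECT_VERBS = ["activates", "represses", "induces", "regulates", "inhibits"]
_EFFECT_POLARITY = {
    "activates": "activation", "induces": "activation",
    "represses": "repression", "inhibits": "repression",
    "regulates": "unspecified",
}


def default_effect_lexicon() -> dict[str, str]:
    """Stem -> polarity map over the fixture effect verbs."""
    from ._porter import stem
    return {stem(v): p for v, p in _EFFECT_POLARITY.items()}


# ---------------------------------------------------------------------------
# corpus with planted entities and topics
# ---------------------------------------------------------------------------

@dataclass
class GeneratedCorpus:
    corpus: list[Document]
    dictionary: list[TermEntry]
    planted_mentions: dict[str, list[EntityMention]]  # doc_id -> mentions
    topic_labels: dict[str, int]  # sent_id -> topic
    effect_lexicon: dict[str, str]


def gen_corpus(spec: FixtureSpec) -> GeneratedCorpus:
    """Template corpus with planted TF/GENE/EFFECT tokens.

    Each sentence belongs to a topic and mixes topic-specific filler words
    with a planted "<TF> <verb> transcription of <gene>" core, so
    dictionary annotation must recover exactly the planted mentions and
    same-topic sentences are closer in bag-of-words space than cross-topic
    ones.
    """
    rng = spec.rng(1)
    tf_names = [f"Tf{w.capitalize()}" for w in _vocab(rng, spec.n_tfs)]
    gene_names = [f"{w}{_CONSONANTS[rng.integers(len(_CONSONANTS))].upper()}"
                  for w in _vocab(rng, spec.n_genes)]
    topics = [_vocab(rng, spec.topic_vocab_size, 3) for _ in range(spec.n_topics)]
    shared = _vocab(rng, spec.shared_vocab_size, 2)

    dictionary = [TermEntry(t, f"TF:{i:03d}", "TF", "synthetic") for i, t in enumerate(tf_names)]
    dictionary += [TermEntry(g, f"G:{i:03d}", "GENE", "synthetic") for i, g in enumerate(gene_names)]

    corpus: list[Document] = []
    planted: dict[str, list[EntityMention]] = {}
    topic_labels: dict[str, int] = {}
    for d in range(spec.n_docs):
        doc_id = f"doc{d:03d}"
        doc_topic = int(rng.integers(spec.n_topics))
        parts: list[str] = []
        spans: list[tuple[int, str, str, str]] = []  # (sent index, tf, verb, gene)
        for s in range(spec.sentences_per_doc):
            topic = doc_topic if rng.random() < 0.8 else int(rng.integers(spec.n_topics))
            if rng.random() < spec.plain_sentence_rate:
                # filler-only sentence: no planted entities, no effect verb
                w = [topics[topic][int(rng.integers(spec.topic_vocab_size))] for _ in range(5)]
                parts.append(f"The {w[0]} {w[1]} level in {w[2]} {w[3]} {w[4]} medium.")
                topic_labels[f"{doc_id}.s{s}"] = topic
                continue
            tf = tf_names[int(rng.integers(spec.n_tfs))]
            gene = gene_names[int(rng.integers(spec.n_genes))]
            verb = _EFFECT_VERBS[int(rng.integers(len(_EFFECT_VERBS)))]
            fillers = [topics[topic][int(rng.integers(spec.topic_vocab_size))] for _ in range(4)]
            glue = shared[int(rng.integers(spec.shared_vocab_size))]
            sentence = (
                f"{tf} {verb} transcription of {gene} under {fillers[0]} "
                f"{fillers[1]} and {fillers[2]} {fillers[3]} {glue}."
            )
            parts.append(sentence)
            spans.append((s, tf, verb, gene))
            topic_labels[f"{doc_id}.s{s}"] = topic
        doc = Document(doc_id=doc_id, text=" ".join(parts))
        preprocess(doc)
        corpus.append(doc)
        ment: list[EntityMention] = []
        for s_idx, tf, verb, gene in spans:
            sent = doc.sentences[s_idx]
            for name, etype, eid in (
                (tf, "TF", f"TF:{tf_names.index(tf):03d}"),
                (gene, "GENE", f"G:{gene_names.index(gene):03d}"),
            ):
                tok_idx = next(i for i, t in enumerate(sent.tokens) if t.surface == name)
                tok = sent.tokens[tok_idx]
                ment.append(EntityMention(
                    doc_id=doc_id, sent_id=sent.sent_id,
                    start_tok=tok_idx, end_tok=tok_idx + 1,
                    char_start=tok.char_start, char_end=tok.char_end,
                    matched_surface=name, candidate_ids=[eid],
                    entity_type=etype, resolved_id=eid,
                ))
        planted[doc_id] = ment
    return GeneratedCorpus(corpus, dictionary, planted, topic_labels, default_effect_lexicon())


# ---------------------------------------------------------------------------
# distant-supervision fixture with planted ambiguity
# ---------------------------------------------------------------------------

@dataclass
class AmbiguousFixture:
    corpus: list[Document]  # training + held-out documents, preprocessed
    dictionary: list[TermEntry]
    links: list[ReferenceLink]  # training split only
    heldout_labels: dict[str, str]  # doc_id -> correct entity_id
    ambiguous_surface: str
    sense_ids: tuple[str, str]


def gen_ambiguous_links(spec: FixtureSpec) -> AmbiguousFixture:
    """Corpus where one surface ("fur"-like) has two senses with disjoint
    context vocabularies; database links cover the training documents, the
    held-out split keeps only its true labels for evaluation."""
    if spec.ambiguity_rate <= 0:
        # still generate, but with a single sense: train_distant on the
        # result must fail for lack of ambiguous instances
        pass
    rng = spec.rng(2)
    surface = "Fur" + _word(rng).capitalize()
    sense_ids = ("E:A", "E:B")
    both = _vocab(rng, 40, 3)  # one draw => the two context vocabularies are disjoint
    ctx_a, ctx_b = both[:20], both[20:]
    dictionary = [
        TermEntry(surface, sense_ids[0], "TF", "synthetic"),
        TermEntry(surface, sense_ids[1], "GENE", "synthetic"),
    ]
    if spec.ambiguity_rate <= 0:
        dictionary = dictionary[:1]

    n_total = spec.n_docs + spec.heldout_docs
    corpus: list[Document] = []
    links: list[ReferenceLink] = []
    heldout: dict[str, str] = {}
    for d in range(n_total):
        doc_id = f"amb{d:03d}"
        sense = d % 2
        ctx = (ctx_a, ctx_b)[sense]
        sents = []
        for _ in range(spec.sentences_per_doc):
            w = [ctx[int(rng.integers(len(ctx)))] for _ in range(5)]
            sents.append(f"The {w[0]} {w[1]} of {surface} with {w[2]} {w[3]} and {w[4]}.")
        doc = Document(doc_id=doc_id, text=" ".join(sents))
        preprocess(doc)
        corpus.append(doc)
        if d < spec.n_docs:
            links.append(ReferenceLink(doc_id, sense_ids[sense] if len(dictionary) > 1 else sense_ids[0]))
        else:
            heldout[doc_id] = sense_ids[sense] if len(dictionary) > 1 else sense_ids[0]
    return AmbiguousFixture(corpus, dictionary, links, heldout, surface, sense_ids)


# ---------------------------------------------------------------------------
# taxonomy + word vectors
# ---------------------------------------------------------------------------

def gen_taxonomy_and_vectors(spec: FixtureSpec) -> tuple[Taxonomy, WordVectors]:
    """Balanced is-a tree with closed-form information content, plus word
    vectors clustered so within-topic words have higher cosine than
    cross-topic words.

    The taxonomy embeds the hand-computable sibling fixture: concepts X
    and Y with p = 0.25 each under Z with p = 0.5 give Lin(X, Y) = 0.5.
    """
    rng = spec.rng(3)
    # root -> (Z, W); Z -> (X, Y). cumulative: X=2, Y=2, Z=4, W=4, root=8
    parents = {"root": [], "Z": ["root"], "W": ["root"], "X": ["Z"], "Y": ["Z"]}
    freqs = {"root": 0.0, "Z": 0.0, "W": 4.0, "X": 2.0, "Y": 2.0}
    word_map: dict[str, list[str]] = {"wx": ["X"], "wy": ["Y"], "wz": ["Z"], "ww": ["W"]}
    # extra leaves under W for variety (do not disturb the closed-form part)
    n_extra = 4
    extra = _vocab(rng, n_extra, 3)
    for i, w in enumerate(extra):
        c = f"W{i}"
        parents[c] = ["W"]
        freqs[c] = 1.0
        freqs["W"] = 0.0
        word_map[w] = [c]
    # rebalance: W cumulative = sum of its leaves = n_extra; scale others
    freqs["X"] = freqs["Y"] = n_extra / 2.0
    taxonomy = Taxonomy(parents, freqs, word_map)

    # vectors: one unit direction per topic, words = direction + small noise
    dirs = rng.normal(size=(spec.n_topics, spec.embedding_dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    vectors: dict[str, list[float]] = {}
    for t in range(spec.n_topics):
        for w in _vocab(spec.rng(40 + t), 10, 3):
            v = dirs[t] + 0.15 * rng.normal(size=spec.embedding_dim)
            vectors[f"t{t}{w}"] = list(v)
    taxonomy_words = list(word_map)
    for i, w in enumerate(taxonomy_words):
        v = dirs[i % spec.n_topics] + 0.15 * rng.normal(size=spec.embedding_dim)
        vectors[w] = list(v)
    return taxonomy, WordVectors(vectors)


# ---------------------------------------------------------------------------
# gold similarity pairs
# ---------------------------------------------------------------------------

def gen_gold_pairs(
    spec: FixtureSpec,
    scorer: Callable[[str, str], float],
    n_pairs: int = 200,
) -> list[GoldPair]:
    """Sentence pairs from a generated corpus with gold = clamp(system
    score + Gaussian(0, sigma), 0, 5); sigma = 0 makes the system's own
    evaluation correlate perfectly."""
    gen = gen_corpus(spec)
    texts = [
        doc.sentence_text(s)
        for doc in gen.corpus
        for s in doc.sentences
    ]
    rng = spec.rng(4)
    pairs: list[GoldPair] = []
    for _ in range(n_pairs):
        i = int(rng.integers(len(texts)))
        j = int(rng.integers(len(texts)))
        if i == j:
            j = (j + 1) % len(texts)
        base = scorer(texts[i], texts[j])
        gold = float(np.clip(base + rng.normal(0.0, spec.noise_sigma), 0.0, 5.0))
        pairs.append(GoldPair(texts[i], texts[j], gold))
    return pairs


# ---------------------------------------------------------------------------
# CoNLL-U emitter for generated corpora
# ---------------------------------------------------------------------------

def corpus_to_conllu(corpus: Sequence[Document]) -> str:
    """Emit a flat dependency parse per sentence.

    The fixture grammar "<TF> <verb> transcription of <gene> ..." is
    parsed by rule: the effect verb is the root, the TF its subject, the
    noun "transcription" its object, and every other token attaches to
    the nearest preceding core node; good enough for exercising LCA
    extraction on generated corpora.
    """
    lines: list[str] = []
    for doc in corpus:
        for sent in doc.sentences:
            toks = sent.tokens
            verb_idx = next(
                (i for i, t in enumerate(toks) if t.surface in _EFFECT_VERBS), 0
            )
            lines.append(f"# sent_id = {sent.sent_id}")
            for i, t in enumerate(toks):
                if i == verb_idx:
                    head, rel = 0, "root"
                elif i < verb_idx:
                    head, rel = verb_idx + 1, "nsubj" if i == verb_idx - 1 else "dep"
                else:
                    head, rel = verb_idx + 1, "obj" if i == verb_idx + 1 else "dep"
                lines.append(
                    f"{i + 1}\t{t.surface}\t_\t_\t_\t_\t{head}\t{rel}\t_\t_"
                )
            lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# writers: every external format a consumer module reads
# ---------------------------------------------------------------------------

def write_fixture_tree(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a full fixture set in the exact on-disk formats the pipeline
    reads; returns the path of every artifact."""
    import pandas as pd
    from .disambiguation import write_links
    from .similarity import write_gold_pairs, combined_similarity

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gen = gen_corpus(spec)
    corpus_dir = out / "corpus"
    corpus_dir.mkdir(exist_ok=True)
    for doc in gen.corpus:
        (corpus_dir / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    paths["corpus"] = corpus_dir

    dict_path = out / "dictionary.tsv"
    pd.DataFrame(
        [{"term": e.term, "entity_id": e.entity_id, "entity_type": e.entity_type,
          "source": e.source} for e in gen.dictionary]
    ).to_csv(dict_path, sep="\t", index=False)
    paths["dictionary"] = dict_path

    effects_path = out / "effects.tsv"
    effects_path.write_text(
        "".join(f"{v}\t{p}\n" for v, p in _EFFECT_POLARITY.items()), encoding="utf-8"
    )
    paths["effects"] = effects_path

    conllu_path = out / "parses.conllu"
    conllu_path.write_text(corpus_to_conllu(gen.corpus), encoding="utf-8")
    paths["conllu"] = conllu_path

    amb = gen_ambiguous_links(spec)
    links_path = out / "links.tsv"
    write_links(amb.links, links_path)
    paths["links"] = links_path

    taxonomy, vectors = gen_taxonomy_and_vectors(spec)
    tax_path, wmap_path = out / "taxonomy.tsv", out / "word_map.tsv"
    taxonomy.write(tax_path, wmap_path)
    paths["taxonomy"], paths["word_map"] = tax_path, wmap_path
    vec_path = out / "vectors.txt"
    vectors.write(vec_path)
    paths["vectors"] = vec_path

    gold_path = out / "gold_pairs.tsv"
    scorer = lambda a, b: combined_similarity(a, b).scaled
    write_gold_pairs(gen_gold_pairs(spec, scorer), gold_path)
    paths["gold_pairs"] = gold_path
    return paths
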