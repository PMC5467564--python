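# curatext

Text-mining building blocks for **semi-automated literature curation** of
regulatory-genomics databases. Database curators read large sets of articles
to extract structured facts — which transcription factor (TF) regulates
which gene, with what effect, under which growth condition. `curatext`
implements the machinery that lets a curator inspect far less text without
missing those facts:

- **Dictionary annotation** (`terminology`) — terms from a reference
  database (genes, TFs, promoters, transcription units) are expanded into
  minor orthographic variants (hyphen/space swaps, case folding above 3
  characters) and matched longest-first over token sequences, preserving
  ambiguity as a candidate-identifier list.
- **Distant-supervision disambiguation** (`disambiguation`) — a multinomial
  naive Bayes classifier resolves ambiguous mentions, trained not on a
  hand-annotated corpus but on the database's own article–entity links:
  if the database cites entity *A* in article *B*, mentions of *A*'s
  surface in *B* are taken as labeled instances.
- **Relation candidates from syntax** (`syntax_relations`) — for a TF
  mention and a gene/TU mention, the interaction trigger is the uppermost
  node shared by their dependency paths (the lowest common ancestor of
  their head tokens); a candidate is kept when that token is a verb or an
  effect word ("induces", "repression", ...). Parses are read from CoNLL-U.
- **Boolean sentence filters** (`filters`) — curator-defined selectors
  such as `type:TF AND lexicon:effect`, with full `AND`/`OR`/`NOT` algebra
  over entity-type, lexicon (stem-matched) and literal-term atoms.
- **Sentence similarity** (`similarity`) — a combination of bag-of-words
  cosine (after Porter stemming), taxonomy-based Lin word similarity
  `2·IC(lcs)/(IC(c1)+IC(c2))` with information content `IC(c) = −log p(c)`,
  and word-embedding cosine, aggregated by symmetrized best-match
  alignment and scaled to the 0–5 STS scale (5 = same meaning). A Pearson
  evaluation harness scores the engine against gold-standard pairs.
- **Cross-document linking** (`linking`) — an offline all-pairs pass links
  sentences about the same subject across articles; a threshold plus a
  per-sentence top-k cap bound the graph, and adding an article updates
  the graph incrementally with a result identical to a full rebuild.
- **Synthetic fixtures** (`synthetic_fixtures`) — seeded generators for
  every input format (corpora, dictionaries, links, CoNLL-U, taxonomy,
  vectors, gold pairs) with planted ground truth, so the whole pipeline
  runs and tests offline.

## Worked example

```python
import curatext as ct
from curatext.syntax_relations import DependencyTree

text = ("Activated OxyR then induces transcription of antioxidant genes, "
        "including katG, ahpCF, and oxyS")
doc = ct.preprocess(ct.Document("example", text))
matcher = ct.compile_dictionary([
    ct.TermEntry("OxyR", "RDB:OXYR", "TF"),
    ct.TermEntry("katG", "RDB:KATG", "GENE"),
    ct.TermEntry("ahpCF", "RDB:AHPCF", "GENE"),
    ct.TermEntry("oxyS", "RDB:OXYS", "GENE"),
])
mentions = ct.annotate(doc, matcher)
for m in mentions:
    print(m.matched_surface, m.entity_type, m.resolved_id)

heads = [2, 4, 4, 0, 4, 8, 8, 5, 11, 11, 8, 13, 11, 16, 16, 11]  # 1-based
tree = DependencyTree([h - 1 if h else -1 for h in heads], ["dep"] * 16)
lex = {ct.stem("induces"): "activation", ct.stem("represses"): "repression"}
for c in ct.extract_relations(doc.sentences[0], tree, mentions, lex):
    print(f"{c.agent.resolved_id} -[{c.trigger_surface}/{c.polarity}]-> "
          f"{c.target.resolved_id}")

s = ct.combined_similarity("OxyR induces transcription of katG",
                           "Transcription of katG is induced by OxyR")
print(f"scaled similarity: {s.scaled:.3f}")
```

prints

```
OxyR TF RDB:OXYR
katG GENE RDB:KATG
ahpCF GENE RDB:AHPCF
oxyS GENE RDB:OXYS
RDB:OXYR -[induces/activation]-> RDB:KATG
RDB:OXYR -[induces/activation]-> RDB:AHPCF
RDB:OXYR -[induces/activation]-> RDB:OXYS
scaled similarity: 4.226
```

The four dictionary terms are found and resolved; the dependency-LCA rule
recovers "induces" as the trigger for all three TF→gene pairs, typed as an
activation; and the two paraphrases of the same regulatory fact score 4.23
of 5 on the STS scale (stemming collapses "induces"/"induced" to one key).

## Command line

Every step is also a subcommand of the `curatext` console script:
`annotate`, `train-disambig`, `relations`, `filter`, `sim`, `sts-eval`,
`link`, `neighbors`, and `synth` (which writes a full synthetic fixture
tree in the exact on-disk formats the other subcommands read). Run
`curatext --help` for options.

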