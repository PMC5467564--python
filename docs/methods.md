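# Methods

This note documents the models and procedures implemented in `curatext`,
the defaults and why they were chosen, what the synthetic fixtures do and
do not emulate, and the known limitations.

## Text normalization

**Offsets.** All annotations use 0-based, half-open character offsets into
the unmodified document text, so every token, mention and sentence span can
be verified by re-slicing. Sentence and token containers never copy text.

**Sentence splitting** is a punctuation–capitalization heuristic: a
boundary is placed after `.`/`!`/`?` followed by whitespace and an
upper-case letter, unless the token carrying the terminator is on an
abbreviation stop-list (`i.e.`, `e.g.`, `et al.`, `Fig.`, ...) or is a
single capital initial — the pattern of genus abbreviations such as
"E. coli", which must never split. Spans are trimmed to non-whitespace, so
every non-whitespace character lies in exactly one sentence.

**Tokenization** produces maximal alphanumeric runs (internal hyphens kept:
"non-specific" is one token, because the terminology matcher handles hyphen
variants itself) and single punctuation marks.

**Stemming** is the classic Porter suffix-stripping cascade, implemented
in-package, lower-cased, applied to a fixed point. A single pass of the
cascade is not idempotent (final-e removal can expose a new strippable
suffix: "agreed" → "agre" → "agr"), and idempotence is a contract other
modules rely on — lexicon entries are stored as stems and must match the
stems of already-stemmed queries. Common inflectional families are stable
after one pass, so on ordinary vocabulary the output agrees with a
single-pass Porter stemmer ("activation"/"activates"/"activated" →
"activ", "transcription" → "transcript").

**POS tagging** uses a coarse 5-label set (NOUN/VERB/ADJ/ADV/OTHER); only
the noun/verb distinction is consumed downstream (the relation-trigger
gate). The default tagger is rule-based — a closed-class lexicon, a
domain verb-stem list ("induce", "repress", "regulate", ...) and suffix
rules — and is deliberately pluggable: any callable mapping tokens to
labels can be dropped in, so a statistical tagger can replace it without
touching consumers. A rule tagger was chosen as the default because it is
deterministic, dependency-free and sufficient for the coarse distinctions
the pipeline needs.

## Terminology matching

Term variants form a closed set: the term, every hyphen↔space swap, the
hyphen-deleted form, and — for terms longer than 3 characters — the
case-folded form of each. The 3-character threshold keeps short gene
symbols case-sensitive ("Fur" vs "fur" can be different entities, while
"ahpCF"/"AhpCF" are safely folded). Plural "-s" stripping exists behind a
flag but is off by default, since inflectional variants are better handled
by stemming in the similarity engine than by dictionary expansion.

Annotation is left-to-right, longest-match-first, non-overlapping, over
token sequences rather than raw substrings so that "oxy" can never fire
inside "oxygen". Ambiguity (one surface, several identifiers) is preserved
on the mention; a mention is resolved immediately only when it has exactly
one candidate.

## Distant-supervision disambiguation

The disambiguator is a multinomial naive Bayes with Laplace smoothing
(default α = 1) over bag-of-feature counts:

- stems of tokens within ±5 tokens of the mention (its own tokens
  excluded);
- entity types of co-mentions in the same sentence (`sent_type=GENE`);
- entity types present elsewhere in the document (`doc_type=TF`).

Training labels come from database article–entity links: a mention whose
candidate set intersects its document's linked entities in **exactly one**
identifier becomes an instance with that label. Two deliberate
restrictions keep the distant-labeling assumption clean: documents whose
links would make a mention's label ambiguous (2+ linked candidates) are
skipped, and only ambiguous mentions (≥2 candidates) are used as training
instances — single-candidate mentions never consult the model, so training
on them would add mass without ever being exercised.

Prediction restricts the posterior to the mention's candidates and
normalizes it; ties (and the all-candidates-unseen case, which is flagged
low-confidence) break to the lexicographically smallest identifier for
determinism. Features absent from the training vocabulary are skipped,
which keeps per-class likelihoods comparable; this matches the standard
multinomial-NB treatment and is cross-checked against scikit-learn's
`MultinomialNB` in the test suite. The model serializes to versioned JSON
with sorted keys, so identical inputs give byte-identical files.

## Relation candidates from dependency parses

For each ordered (TF, gene/TU) mention pair in a sentence, the candidate
trigger is the lowest common ancestor of the two mentions' head tokens in
the dependency tree — the uppermost node where the two syntactic paths
meet. The mention head is its last token (English noun phrases are
right-headed). A candidate is emitted only if the LCA token is tagged VERB
**or** its stem is in the effect lexicon; the lexicon disjunct keeps
nominalizations ("activation of X by Y") that a verb-only gate would lose.
Polarity is the lexicon class of the trigger stem ("activation",
"repression") or "unspecified". Agent/target roles are assigned by entity
type (TF → agent), not by dependency labels; label-driven role assignment
is noted as future work. Parses are consumed from CoNLL-U, never produced.

## Filters

A filter is a boolean expression over one sentence's annotations, with
atoms `type:<ENTITY_TYPE>` (≥1 mention of that type), `lexicon:<name>`
(≥1 token matching the named lexicon) and `term:"<literal>"` (substring of
the sentence text). Precedence is NOT > AND > OR, left-associative;
keywords are case-insensitive, atom payloads case-sensitive. Lexicon atoms
match on stems by default so one entry ("activ") covers the whole
inflectional family ("activates", "activation"); surface matching is
available per lexicon. Expressions round-trip through a canonical printer,
and syntax errors carry a character position.

## Sentence similarity

Three signals, each in [0, 1]:

- **VSM cosine** — sparse bag-of-words counts over alphabetic tokens after
  lower-casing and stemming (stopword removal is available but off by
  default); cosine of the two count vectors, defined as 0 when either is
  empty. Raw counts are used; cosine is scale-invariant, so count
  normalization would be a no-op.
- **Lin (taxonomy)** — `2·IC(lcs) / (IC(c1) + IC(c2))` with
  `IC(c) = −log p(c)`, `p` from cumulative descendant frequencies over an
  is-a DAG with a single root (`IC(root) = 0`). The lowest common subsumer
  in a DAG is the common ancestor-or-self with maximal IC; ambiguous words
  take the maximum over their concept pairs (the conventional choice when
  no sense disambiguation is available). Out-of-vocabulary words score 0.
- **Embedding** — cosine of dense word vectors, clamped by `max(0, ·)`:
  a negative cosine carries no similarity signal for this use, and the
  alternative rescaling `(cos+1)/2` would award 0.5 to orthogonal words.

The two word-level signals are lifted to sentence level by symmetrized
greedy best-match alignment: each word's best-match similarity in the
other sentence, averaged, in both directions. This is the standard
linear-time STS baseline and is deterministic.

Enabled metrics are combined by a weighted arithmetic mean (default: VSM
only; equal weights when several are enabled) and scaled by 5 to the STS
scale, where 5 means the sentences convey the same meaning and 0 that they
are unrelated. Evaluation against gold pairs uses the Pearson
product-moment correlation; inputs with zero variance are rejected rather
than silently yielding NaN.

## Cross-document linking

All sentence pairs (optionally excluding same-document pairs) are scored
with the combined similarity; pairs at or above a scaled-score threshold
are kept, then each sentence's links are capped at its `top_k` best. The
cap is mutual — a link survives if it is within top_k for **at least one**
endpoint — which preserves graph symmetry. Defaults: threshold 3.5/5,
top_k 10; both bound graph size on dense topical corpora and are recorded
in the graph's config snapshot.

`add_document` scores only the pairs touching the new document and merges
them with the stored raw (thresholded, uncapped) link list before
re-deriving the cap, so the incremental result is identical to a batch
rebuild; the raw list is serialized alongside the capped view so the
equivalence survives a save/load round-trip. All-pairs O(n²) scoring is
accepted at desk scale; no approximate nearest-neighbor index is used.

## Synthetic fixtures

The generators emulate the statistical and lexical structure the pipeline
consumes, not natural language. Sentences are template-generated
("<TF> <effect-verb> transcription of <gene> under <topic fillers>...")
from per-topic vocabularies of pronounceable nonsense words, with planted
mention offsets and per-sentence topic labels returned alongside; roughly
a quarter of sentences are entity-free filler so selection tasks are
non-trivial. The disambiguation fixture plants one ambiguous surface whose
two senses have disjoint context vocabularies — separable by construction,
so held-out accuracy is expected to be high (≥ 0.9 at the default sizes of
40 training and 10 held-out documents). The taxonomy fixture embeds a
closed-form sibling pair (cumulative probabilities ¼, ¼ under ½, giving
Lin = 0.5 exactly); gold similarity pairs are the system's own score plus
clamped Gaussian noise (σ = 0.3 by default, the scale of a small
disagreement on the 0–5 scale).

Because the fixtures are planted and separable, passing tests demonstrate
the *mechanics* — offsets, matching, posterior arithmetic, graph
equivalences — not performance on real biomedical prose, where entity
boundaries are noisier, contexts overlap, and parses are imperfect.
Everything is driven by a seeded `FixtureSpec`; the same spec produces
byte-identical outputs.

## Problem sizes

The oracle batteries run 500 random filter cases, 1000 random dependency
trees, 1000 random sentence pairs, a 50-document disambiguation fixture,
200 gold pairs and 30–100 incremental-linking trials; the whole test suite
and the acceptance script each complete in well under a minute on one
core. These sizes were chosen to exercise every code path and give stable
fraction estimates while keeping the feedback loop fast.

## Known limitations

- No fuzzy or abbreviation-aware term matching; a misspelled gene symbol
  is missed.
- The rule POS tagger is coarse; an unusual verb absent from the stem list
  and suffix rules falls back to OTHER, which can suppress a relation
  candidate unless the effect lexicon covers the trigger.
- Relation extraction has no negation or speculation handling and no
  coreference; roles are type-driven.
- The Lin metric's max-over-senses choice can overstate similarity for
  highly ambiguous words.
- Linking is quadratic in corpus sentence count; fine for curation-sized
  corpora (thousands of sentences), not for web-scale collections.
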