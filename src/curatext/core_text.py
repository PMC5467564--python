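"""Text data model, corpus I/O and linguistic normalization.

The backbone types (:class:`Token`, :class:`Sentence`, :class:`Document`) use
0-based half-open character offsets into the original document text, so every
annotation can be verified by re-slicing: ``doc.text[t.char_start:t.char_end]
== t.surface`` always holds.

Normalization covers sentence splitting (punctuation + capitalization
heuristic with an abbreviation stop-list), tokenization (alphanumeric runs
with internal hyphens, single punctuation marks), Porter stemming and a
pluggable coarse part-of-speech tagger.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from ._porter import stem as _porter_stem

#: The coarse POS inventory. Only the NOUN/VERB distinction is consumed
#: downstream (relation-trigger gating), so a five-label set suffices.
POS_LABELS = ("NOUN", "VERB", "ADJ", "ADV", "OTHER")


@dataclass
class Token:
    surface: str
    char_start: int
    char_end: int
    stem: str = ""
    pos: str = "OTHER"


@dataclass
class Sentence:
    sent_id: str
    doc_id: str
    index: int
    char_start: int
    char_end: int
    tokens: list[Token] = field(default_factory=list)


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)

    def sentence_text(self, sentence: Sentence) -> str:
        return self.text[sentence.char_start:sentence.char_end]


@dataclass(frozen=True)
class Lexicon:
    """A named word list matched on surfaces or on stems.

    When ``match_on == "stem"`` all entries are stored lower-cased (stems are
    lower-case by construction).
    """

    name: str
    entries: frozenset[str]
    match_on: str = "stem"  # "surface" | "stem"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"lexicon {self.name!r} has no entries")
        if self.match_on not in ("surface", "stem"):
            raise ValueError(f"match_on must be 'surface' or 'stem', got {self.match_on!r}")
        if self.match_on == "stem":
            object.__setattr__(self, "entries", frozenset(e.lower() for e in self.entries))

    @classmethod
    def from_file(cls, name: str, path: str | Path, match_on: str = "stem") -> "Lexicon":
        lines = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()]
        return cls(name, frozenset(ln for ln in lines if ln), match_on)

    def contains_token(self, token: Token) -> bool:
        if self.match_on == "stem":
            return token.stem in self.entries
        return token.surface in self.entries


# ---------------------------------------------------------------------------
# corpus I/O
# ---------------------------------------------------------------------------

def read_corpus(path: str | Path, format: str = "txt-dir") -> list[Document]:
    """Read a corpus as one :class:`Document` per record.

    ``txt-dir``: every ``*.txt`` file in the directory becomes a document
    whose id is the filename stem. ``tsv``: a table with columns
    ``doc_id`` and ``text``. Text is preserved byte-for-byte; sentences are
    not split here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    docs: list[Document] = []
    if format == "txt-dir":
        for f in sorted(path.glob("*.txt")):
            docs.append(Document(doc_id=f.stem, text=f.read_text(encoding="utf-8")))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = {"doc_id", "text"} - set(df.columns)
        if missing:
            raise ValueError(f"tsv corpus missing columns: {sorted(missing)}")
        for row in df.itertuples(index=False):
            docs.append(Document(doc_id=row.doc_id, text=row.text))
    else:
        raise ValueError(f"unknown corpus format {format!r}")

    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValueError(f"duplicate doc_id {d.doc_id!r}")
        seen.add(d.doc_id)
    if not docs:
        raise ValueError(f"empty corpus at {path}")
    return docs


# ---------------------------------------------------------------------------
# sentence splitting
# ---------------------------------------------------------------------------

#: Abbreviations that never end a sentence even when followed by whitespace
#: and a capital ("E. coli", "i.e.", "et al.", figure references ...).
ABBREVIATIONS = frozenset({
    "i.e.", "e.g.", "cf.", "vs.", "et", "al.", "et al.", "fig.", "figs.",
    "ref.", "refs.", "no.", "approx.", "ca.", "sp.", "spp.", "str.",
})

_SINGLE_INITIAL = re.compile(r"^[A-Z]\.$")


def _is_abbreviation(run: str) -> bool:
    """``run`` is the maximal non-whitespace run ending at the terminator."""
    if _SINGLE_INITIAL.match(run):
        return True  # genus initials: "E. coli", "S. typhimurium"
    return run.lower() in ABBREVIATIONS


def split_sentences(document: Document) -> Document:
    """Populate ``document.sentences`` in place (and return the document).

    Boundaries are placed after sentence-final ``. ! ?`` followed by
    whitespace and an upper-case letter, unless the token carrying the
    terminator is a known abbreviation. Text without a terminator is a
    single sentence. Spans are trimmed to non-whitespace, so every
    non-whitespace character lies inside exactly one sentence span.
    """
    text = document.text
    if not text.strip():
        document.sentences = []
        return document
    boundaries: list[int] = []
    for m in re.finditer(r"[.!?]", text):
        i = m.end()
        # must be followed by whitespace then an upper-case letter
        j = i
        while j < len(text) and text[j].isspace():
            j += 1
        if j == i or j >= len(text) or not text[j].isupper():
            continue
        run_start = m.start()
        while run_start > 0 and not text[run_start - 1].isspace():
            run_start -= 1
        if _is_abbreviation(text[run_start:i]):
            continue
        boundaries.append(i)

    spans: list[tuple[int, int]] = []
    prev = 0
    for b in boundaries + [len(text)]:
        seg = text[prev:b]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append((prev + lead, b - trail))
        prev = b

    document.sentences = [
        Sentence(
            sent_id=f"{document.doc_id}.s{k}",
            doc_id=document.doc_id,
            index=k,
            char_start=s,
            char_end=e,
        )
        for k, (s, e) in enumerate(spans)
    ]
    return document


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*|[^\sA-Za-z0-9]")


def tokenize(sentence_text: str, offset: int = 0) -> list[Token]:
    """Tokenize into maximal alphanumeric runs (internal hyphens kept) and
    single punctuation marks; offsets are document-absolute via ``offset``."""
    return [
        Token(surface=m.group(), char_start=offset + m.start(), char_end=offset + m.end())
        for m in _TOKEN_RE.finditer(sentence_text)
    ]


def stem(word: str) -> str:
    """Porter stem, lower-cased; idempotent and deterministic."""
    return _porter_stem(word)


# ---------------------------------------------------------------------------
# part-of-speech tagging
# ---------------------------------------------------------------------------

PosTagger = Callable[[Sequence[Token]], list[str]]

_CLOSED_CLASS = {
    # determiners / prepositions / conjunctions / pronouns -> OTHER
    "the": "OTHER", "a": "OTHER", "an": "OTHER", "this": "OTHER",
    "that": "OTHER", "these": "OTHER", "those": "OTHER", "of": "OTHER",
    "in": "OTHER", "on": "OTHER", "at": "OTHER", "by": "OTHER",
    "from": "OTHER", "to": "OTHER", "with": "OTHER", "for": "OTHER",
    "as": "OTHER", "into": "OTHER", "within": "OTHER", "across": "OTHER",
    "between": "OTHER", "and": "OTHER", "or": "OTHER", "but": "OTHER",
    "including": "OTHER", "it": "OTHER", "its": "OTHER", "they": "OTHER",
    "their": "OTHER", "we": "OTHER", "which": "OTHER", "who": "OTHER",
    # copulas / auxiliaries -> VERB
    "is": "VERB", "are": "VERB", "was": "VERB", "were": "VERB", "be": "VERB",
    "been": "VERB", "has": "VERB", "have": "VERB", "had": "VERB",
    "can": "VERB", "could": "VERB", "may": "VERB", "will": "VERB",
    "would": "VERB", "does": "VERB", "do": "VERB", "did": "VERB",
    # frequent adverbs
    "then": "ADV", "also": "ADV", "thus": "ADV", "not": "ADV",
    "only": "ADV", "very": "ADV",
}

#: Stems of verbs common in regulatory-genomics prose; any token whose Porter
#: stem is in this set is tagged VERB regardless of suffix.
_VERB_STEMS = frozenset(map(_porter_stem, (
    "induce", "activate", "repress", "regulate", "inhibit", "bind", "encode",
    "express", "transcribe", "control", "increase", "decrease", "suppress",
    "stimulate", "mediate", "require", "promote", "upregulate",
    "downregulate", "protect", "assist", "grow", "divide", "respond",
    "produce", "affect", "modulate", "enhance", "reduce",
)))

_NOUN_SUFFIXES = ("tion", "sion", "ment", "ness", "ity", "ance", "ence", "ism", "ase")
_ADJ_SUFFIXES = ("ous", "ive", "al", "ic", "able", "ible", "ant", "ent", "ary")


def _rule_tag_one(token: Token) -> str:
    surf = token.surface
    low = surf.lower()
    if not any(c.isalpha() for c in surf):
        return "OTHER"
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    st = token.stem or _porter_stem(surf)
    if st in _VERB_STEMS:
        return "VERB"
    if low.endswith("ly"):
        return "ADV"
    if low.endswith(_NOUN_SUFFIXES):
        return "NOUN"
    if low.endswith(_ADJ_SUFFIXES):
        return "ADJ"
    return "OTHER"


def rule_based_tagger(tokens: Sequence[Token]) -> list[str]:
    """Default coarse tagger: closed-class lexicon, a verb-stem list and
    suffix rules; unknown tokens fall back to OTHER."""
    return [_rule_tag_one(t) for t in tokens]


def pos_tag(tokens: Sequence[Token], tagger: PosTagger | None = None) -> Sequence[Token]:
    """Fill ``token.pos`` for every token using ``tagger`` (default:
    :func:`rule_based_tagger`); any statistical tagger with the same
    signature can be dropped in."""
    labels = (tagger or rule_based_tagger)(tokens)
    for tok, label in zip(tokens, labels):
        if label not in POS_LABELS:
            raise ValueError(f"tagger produced unknown label {label!r}")
        tok.pos = label
    return tokens


# ---------------------------------------------------------------------------
# pipeline convenience
# ---------------------------------------------------------------------------

def preprocess(document: Document, tagger: PosTagger | None = None) -> Document:
    """Split sentences, tokenize, stem and POS-tag a document in place."""
    split_sentences(document)
    for sent in document.sentences:
        sent.tokens = tokenize(document.sentence_text(sent), offset=sent.char_start)
        for tok in sent.tokens:
            tok.stem = _porter_stem(tok.surface)
        pos_tag(sent.tokens, tagger)
    return document


def preprocess_corpus(corpus: Iterable[Document], tagger: PosTagger | None = None) -> list[Document]:
    return [preprocess(d, tagger) for d in corpus]
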