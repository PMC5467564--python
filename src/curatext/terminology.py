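"""Dictionary compilation and longest-match entity annotation.

A terminology dictionary maps surface terms to reference-database
identifiers (genes, transcription factors, promoters, transcription units,
effect words ...). Each term is expanded into a closed set of minor
orthographic variants (hyphen/space swaps, hyphen deletion, case folding
for terms longer than three characters), and documents are annotated by
left-to-right, longest-match-first, non-overlapping matching over token
sequences. Ambiguity — one surface, several identifiers — is preserved on
the mention as ``candidate_ids`` and resolved later (see
:mod:`curatext.disambiguation`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_text import Document, Sentence, tokenize

#: Terms of at most this many characters are matched case-sensitively
#: (short gene symbols such as "fur" or "Fur" are case-informative).
CASE_SENSITIVE_MAX_LEN = 3


@dataclass(frozen=True)
class TermEntry:
    term: str
    entity_id: str
    entity_type: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("empty term")


@dataclass
class EntityMention:
    doc_id: str
    sent_id: str
    start_tok: int  # token span, half-open, sentence-local
    end_tok: int
    char_start: int
    char_end: int
    matched_surface: str
    candidate_ids: list[str]
    entity_type: str
    resolved_id: str | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.candidate_ids:
            raise ValueError("candidate_ids must be non-empty")
        if self.resolved_id is not None and self.resolved_id not in self.candidate_ids:
            raise ValueError("resolved_id must be one of candidate_ids")


def expand_variants(term: str, strip_plural_s: bool = False) -> set[str]:
    """Closed set of minor orthographic variants of ``term``.

    Always contains the term itself, every hyphen<->space swap, the
    hyphen-deleted form, and (for terms longer than
    ``CASE_SENSITIVE_MAX_LEN``) the case-folded form of each of those.
    ``strip_plural_s`` additionally adds de-pluralized forms; it is off by
    default. The set is closed: expanding any member yields no new strings.
    """
    out: set[str] = set()
    frontier = {term}
    while frontier:
        t = frontier.pop()
        if t in out or not t:
            continue
        out.add(t)
        if "-" in t:
            frontier.add(t.replace("-", " "))
            frontier.add(t.replace("-", ""))
        if " " in t:
            frontier.add(t.replace(" ", "-"))
        if len(t) > CASE_SENSITIVE_MAX_LEN:
            frontier.add(t.lower())
        if strip_plural_s and t.endswith("s") and len(t) > 3:
            frontier.add(t[:-1])
    return out


class Matcher:
    """Token-sequence index over all variants of all dictionary entries.

    Matching is over token sequences, not raw substrings, so "oxy" can
    never fire inside "oxygen". Terms longer than
    ``CASE_SENSITIVE_MAX_LEN`` characters are matched case-insensitively;
    shorter terms exactly.
    """

    def __init__(self, entries: Sequence[TermEntry], strip_plural_s: bool = False):
        if not entries:
            raise ValueError("cannot compile an empty dictionary")
        seen_pairs: set[tuple[str, str]] = set()
        for e in entries:
            key = (e.term, e.entity_id)
            if key in seen_pairs:
                raise ValueError(f"duplicate (term, entity_id) pair {key}")
            seen_pairs.add(key)
        self.entries = list(entries)
        # exact-surface index (short terms) and case-folded index (long terms)
        self._exact: dict[tuple[str, ...], list[TermEntry]] = {}
        self._folded: dict[tuple[str, ...], list[TermEntry]] = {}
        self.max_len = 1
        for e in entries:
            for variant in expand_variants(e.term, strip_plural_s):
                toks = tuple(t.surface for t in tokenize(variant))
                if not toks:
                    continue
                self.max_len = max(self.max_len, len(toks))
                if len(variant) <= CASE_SENSITIVE_MAX_LEN:
                    self._exact.setdefault(toks, []).append(e)
                else:
                    folded = tuple(t.lower() for t in toks)
                    self._folded.setdefault(folded, []).append(e)

    def lookup(self, surfaces: Sequence[str]) -> list[TermEntry]:
        """Entries whose some variant tokenizes to ``surfaces``."""
        key = tuple(surfaces)
        hits = list(self._exact.get(key, ()))
        hits += self._folded.get(tuple(s.lower() for s in key), ())
        # de-duplicate while keeping order (a variant may live in both maps)
        seen: set[tuple[str, str]] = set()
        out = []
        for e in hits:
            k = (e.term, e.entity_id)
            if k not in seen:
                seen.add(k)
                out.append(e)
        return out


def compile_dictionary(entries: Sequence[TermEntry], strip_plural_s: bool = False) -> Matcher:
    """Build a :class:`Matcher`; variants of distinct entries may collide —
    ambiguity is preserved, never resolved here."""
    return Matcher(entries, strip_plural_s)


def read_dictionary(path: str | Path) -> list[TermEntry]:
    """Read a dictionary TSV with columns term, entity_id, entity_type, source."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"term", "entity_id", "entity_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dictionary missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = ""
    return [
        TermEntry(r.term, r.entity_id, r.entity_type, r.source)
        for r in df.itertuples(index=False)
    ]


def _annotate_sentence(doc: Document, sent: Sentence, matcher: Matcher) -> list[EntityMention]:
    toks = sent.tokens
    mentions: list[EntityMention] = []
    i = 0
    n = len(toks)
    while i < n:
        hit = None
        for length in range(min(matcher.max_len, n - i), 0, -1):
            window = [t.surface for t in toks[i:i + length]]
            entries = matcher.lookup(window)
            if entries:
                hit = (length, entries)
                break
        if hit is None:
            i += 1
            continue
        length, entries = hit
        ids = sorted({e.entity_id for e in entries})
        # if one entity_type dominates use it; ties joined for transparency
        types = sorted({e.entity_type for e in entries})
        mention = EntityMention(
            doc_id=doc.doc_id,
            sent_id=sent.sent_id,
            start_tok=i,
            end_tok=i + length,
            char_start=toks[i].char_start,
            char_end=toks[i + length - 1].char_end,
            matched_surface=doc.text[toks[i].char_start:toks[i + length - 1].char_end],
            candidate_ids=ids,
            entity_type=types[0] if len(types) == 1 else ";".join(types),
            resolved_id=ids[0] if len(ids) == 1 else None,
        )
        mentions.append(mention)
        i += length
    return mentions


def annotate(document: Document, matcher: Matcher) -> list[EntityMention]:
    """Annotate a preprocessed document.

    Left-to-right, longest-match-first, non-overlapping matching over each
    sentence's token sequence. Every mention carries all candidate
    identifiers; ``resolved_id`` is set immediately iff there is exactly
    one candidate.
    """
    mentions: list[EntityMention] = []
    for sent in document.sentences:
        mentions.extend(_annotate_sentence(document, sent, matcher))
    return mentions


def annotate_corpus(corpus: Iterable[Document], matcher: Matcher) -> dict[str, list[EntityMention]]:
    """Per-document annotation map ``doc_id -> mentions``."""
    return {doc.doc_id: annotate(doc, matcher) for doc in corpus}


def write_annotations(mentions: Iterable[EntityMention], path: str | Path) -> None:
    """Write the annotation TSV: doc_id, sent_id, char_start, char_end,
    surface, entity_type, candidate_ids (semicolon-joined), resolved_id."""
    rows = [
        {
            "doc_id": m.doc_id,
            "sent_id": m.sent_id,
            "char_start": m.char_start,
            "char_end": m.char_end,
            "surface": m.matched_surface,
            "entity_type": m.entity_type,
            "candidate_ids": ";".join(m.candidate_ids),
            "resolved_id": m.resolved_id or "",
        }
        for m in mentions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
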