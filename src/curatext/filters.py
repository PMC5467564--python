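"""Boolean sentence filters over entity annotations and lexicon matches.

A filter is a selector of sentences satisfying a logical condition, e.g.
``type:TF AND lexicon:effect`` — at least one transcription-factor mention
and at least one effect word in the same sentence. The grammar is

    expr   := or
    or     := and  ( OR and )*
    and    := not  ( AND not )*
    not    := NOT not | atom | "(" expr ")"
    atom   := "type:" NAME | "lexicon:" NAME | 'term:"..."'

with precedence NOT > AND > OR, left-associative; the keywords are
case-insensitive, atom payloads case-sensitive. Lexicon atoms match on
token stems by default (so "activates" and "activation" both hit an
"activ" entry) — see :class:`curatext.core_text.Lexicon`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_text import Document, Lexicon, Sentence
from .terminology import EntityMention


class FilterExpr:
    """Base class of the expression tree; see subclasses."""

    def to_string(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Atom(FilterExpr):
    kind: str  # "type" | "lexicon" | "term"
    value: str

    def to_string(self) -> str:
        if self.kind == "term":
            return f'term:"{self.value}"'
        return f"{self.kind}:{self.value}"


@dataclass(frozen=True)
class Not(FilterExpr):
    operand: FilterExpr

    def to_string(self) -> str:
        return f"NOT {_maybe_paren(self.operand, Atom, Not)}"


@dataclass(frozen=True)
class And(FilterExpr):
    left: FilterExpr
    right: FilterExpr

    def to_string(self) -> str:
        return (
            f"{_maybe_paren(self.left, Atom, Not, And)} AND "
            f"{_maybe_paren(self.right, Atom, Not)}"
        )


@dataclass(frozen=True)
class Or(FilterExpr):
    left: FilterExpr
    right: FilterExpr

    def to_string(self) -> str:
        return (
            f"{_maybe_paren(self.left, Atom, Not, And, Or)} OR "
            f"{_maybe_paren(self.right, Atom, Not, And)}"
        )


def _maybe_paren(e: FilterExpr, *bare: type) -> str:
    s = e.to_string()
    return s if isinstance(e, bare) else f"({s})"


class FilterSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


@dataclass(frozen=True)
class _Tok:
    kind: str  # AND OR NOT LPAREN RPAREN ATOM END
    value: str
    pos: int


def _lex(expr: str) -> list[_Tok]:
    toks: list[_Tok] = []
    i = 0
    n = len(expr)
    while i < n:
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c == "(":
            toks.append(_Tok("LPAREN", c, i)); i += 1
            continue
        if c == ")":
            toks.append(_Tok("RPAREN", c, i)); i += 1
            continue
        # a word: keyword or atom
        j = i
        while j < n and not expr[j].isspace() and expr[j] not in "()":
            if expr[j] == '"':  # quoted term payload may contain anything
                j += 1
                while j < n and expr[j] != '"':
                    j += 1
                if j >= n:
                    raise FilterSyntaxError("unterminated quote", i)
            j += 1
        word = expr[i:j]
        up = word.upper()
        if up in ("AND", "OR", "NOT"):
            toks.append(_Tok(up, word, i))
        else:
            toks.append(_Tok("ATOM", word, i))
        i = j
    toks.append(_Tok("END", "", n))
    return toks


def _parse_atom_payload(word: str, pos: int) -> Atom:
    if word.startswith("type:"):
        name = word[len("type:"):]
        if not name:
            raise FilterSyntaxError("empty type name", pos)
        return Atom("type", name)
    if word.startswith("lexicon:"):
        name = word[len("lexicon:"):]
        if not name:
            raise FilterSyntaxError("empty lexicon name", pos)
        return Atom("lexicon", name)
    if word.startswith("term:"):
        payload = word[len("term:"):]
        if len(payload) >= 2 and payload[0] == '"' and payload[-1] == '"':
            payload = payload[1:-1]
        if not payload:
            raise FilterSyntaxError("empty term literal", pos)
        return Atom("term", payload)
    raise FilterSyntaxError(f"unknown atom {word!r}", pos)


class _Parser:
    def __init__(self, tokens: list[_Tok], lexicons: Mapping[str, Lexicon] | None):
        self.toks = tokens
        self.i = 0
        self.lexicons = lexicons

    def peek(self) -> _Tok:
        return self.toks[self.i]

    def next(self) -> _Tok:
        t = self.toks[self.i]
        self.i += 1
        return t

    def parse(self) -> FilterExpr:
        e = self.parse_or()
        t = self.peek()
        if t.kind != "END":
            raise FilterSyntaxError(f"unexpected {t.value!r}", t.pos)
        return e

    def parse_or(self) -> FilterExpr:
        e = self.parse_and()
        while self.peek().kind == "OR":
            self.next()
            e = Or(e, self.parse_and())
        return e

    def parse_and(self) -> FilterExpr:
        e = self.parse_not()
        while self.peek().kind == "AND":
            self.next()
            e = And(e, self.parse_not())
        return e

    def parse_not(self) -> FilterExpr:
        t = self.peek()
        if t.kind == "NOT":
            self.next()
            return Not(self.parse_not())
        if t.kind == "LPAREN":
            self.next()
            try:
                e = self.parse_or()
            except FilterSyntaxError as err:
                if self.peek().kind == "END":  # ran off the end inside parens
                    raise FilterSyntaxError("unbalanced parenthesis", t.pos) from err
                raise
            closing = self.peek()
            if closing.kind != "RPAREN":
                raise FilterSyntaxError("unbalanced parenthesis", t.pos)
            self.next()
            return e
        if t.kind == "ATOM":
            self.next()
            atom = _parse_atom_payload(t.value, t.pos)
            if atom.kind == "lexicon" and self.lexicons is not None and atom.value not in self.lexicons:
                raise FilterSyntaxError(f"unknown lexicon {atom.value!r}", t.pos)
            return atom
        raise FilterSyntaxError(f"expected an atom, NOT or '(', got {t.value or 'end of input'!r}", t.pos)


def parse_filter(expr: str, lexicons: Mapping[str, Lexicon] | None = None) -> FilterExpr:
    """Parse a filter expression; syntax errors carry a character position.

    If ``lexicons`` is given, referencing an unregistered lexicon name is
    an error. The result round-trips through :meth:`FilterExpr.to_string`.
    """
    return _Parser(_lex(expr), lexicons).parse()


def eval_filter(
    expr: FilterExpr,
    sentence: Sentence,
    mentions: Sequence[EntityMention],
    lexicons: Mapping[str, Lexicon] | None = None,
    sentence_text: str = "",
) -> bool:
    """Evaluate a filter against one annotated sentence.

    Atoms see only this sentence's mentions and tokens: ``type:T`` is true
    iff some mention of entity type T lies in the sentence, ``lexicon:L``
    iff some token matches lexicon L (on stems or surfaces per the lexicon
    config), ``term:"x"`` iff the literal string occurs in the sentence
    text.
    """
    lexicons = lexicons or {}
    if isinstance(expr, Atom):
        if expr.kind == "type":
            return any(
                m.sent_id == sentence.sent_id and expr.value in m.entity_type.split(";")
                for m in mentions
            )
        if expr.kind == "lexicon":
            if expr.value not in lexicons:
                raise KeyError(f"lexicon {expr.value!r} not registered")
            lx = lexicons[expr.value]
            return any(lx.contains_token(t) for t in sentence.tokens)
        if expr.kind == "term":
            return expr.value in sentence_text
        raise ValueError(f"unknown atom kind {expr.kind!r}")
    if isinstance(expr, Not):
        return not eval_filter(expr.operand, sentence, mentions, lexicons, sentence_text)
    if isinstance(expr, And):
        return eval_filter(expr.left, sentence, mentions, lexicons, sentence_text) and eval_filter(
            expr.right, sentence, mentions, lexicons, sentence_text
        )
    if isinstance(expr, Or):
        return eval_filter(expr.left, sentence, mentions, lexicons, sentence_text) or eval_filter(
            expr.right, sentence, mentions, lexicons, sentence_text
        )
    raise TypeError(f"not a FilterExpr: {expr!r}")


def select_sentences(
    corpus: Iterable[Document],
    expr: FilterExpr,
    annotations: Mapping[str, Sequence[EntityMention]],
    lexicons: Mapping[str, Lexicon] | None = None,
) -> tuple[list[tuple[str, str]], float]:
    """All (doc_id, sent_id) whose sentence satisfies ``expr``, in corpus
    order, plus the selected fraction of all sentences (0.0 for an empty
    corpus)."""
    selected: list[tuple[str, str]] = []
    total = 0
    for doc in corpus:
        mentions = annotations.get(doc.doc_id, ())
        for sent in doc.sentences:
            total += 1
            if eval_filter(expr, sent, mentions, lexicons, doc.sentence_text(sent)):
                selected.append((doc.doc_id, sent.sent_id))
    fraction = len(selected) / total if total else 0.0
    return selected, fraction
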