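"""Relation-candidate extraction from dependency parses.

The extraction rule mirrors how an interaction verb surfaces in a
dependency tree: for a pair of entity mentions (a transcription factor and
a regulated gene or transcription unit), the token that expresses their
interaction is the uppermost node shared by the syntactic paths from the
root to the two arguments — i.e. the lowest common ancestor (LCA) of their
head tokens. A candidate is emitted only when that LCA token is a verb or
its stem belongs to the effect lexicon (so nominalizations such as
"activation of X by Y" are kept).

Parses are consumed from CoNLL-U files, never produced here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .core_text import Sentence, stem as porter_stem
from .terminology import EntityMention

#: entity types acting as the agent / the target of a regulatory relation
AGENT_TYPES = frozenset({"TF"})
TARGET_TYPES = frozenset({"GENE", "TU"})


@dataclass
class DependencyTree:
    """Heads and relation labels aligned 1:1 with a sentence's tokens.

    ``heads[i]`` is the 0-based index of token i's head; the single root
    has the sentinel head -1.
    """

    heads: list[int]
    deprels: list[str]

    def __post_init__(self) -> None:
        n = len(self.heads)
        if len(self.deprels) != n:
            raise ValueError("heads and deprels must have equal length")
        roots = [i for i, h in enumerate(self.heads) if h == -1]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for i, h in enumerate(self.heads):
            if h != -1 and not (0 <= h < n):
                raise ValueError(f"head index {h} of token {i} out of range")
        # cycle check: walk every root path
        for i in range(n):
            seen = set()
            j = i
            while j != -1:
                if j in seen:
                    raise ValueError(f"cycle in head links involving token {i}")
                seen.add(j)
                j = self.heads[j]

    def __len__(self) -> int:
        return len(self.heads)

    def root_path(self, index: int) -> list[int]:
        """Token indices from ``index`` up to and including the root."""
        path = [index]
        while self.heads[path[-1]] != -1:
            path.append(self.heads[path[-1]])
        return path


@dataclass
class RelationCandidate:
    agent: EntityMention
    target: EntityMention
    trigger_index: int
    trigger_surface: str
    trigger_stem: str
    polarity: str = "unspecified"


def read_conllu(
    path: str | Path,
    expected_tokens: Mapping[str, int] | None = None,
) -> dict[str, DependencyTree]:
    """Read CoNLL-U into ``sent_id -> DependencyTree``.

    Sentence ids come from ``# sent_id = ...`` comments. Multiword-token
    and empty-node lines (ids containing "-" or ".") are skipped.
    ``expected_tokens`` (sent_id -> token count, e.g. from the corpus
    tokenization) makes mismatches an error naming the sentence.
    """
    trees: dict[str, DependencyTree] = {}
    sent_id: str | None = None
    heads: list[int] = []
    deprels: list[str] = []

    def flush() -> None:
        nonlocal sent_id, heads, deprels
        if heads:
            if sent_id is None:
                raise ValueError("CoNLL-U sentence without a '# sent_id =' comment")
            if sent_id in trees:
                raise ValueError(f"duplicate sent_id {sent_id!r} in CoNLL-U file")
            trees[sent_id] = DependencyTree(heads, deprels)
        sent_id, heads, deprels = None, [], []

    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            if line[1:].split("=", 1)[0].strip() == "sent_id":
                sent_id = line.split("=", 1)[1].strip()
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ValueError(f"line {lineno}: expected >= 8 tab-separated columns")
        if "-" in cols[0] or "." in cols[0]:
            continue
        idx = int(cols[0])
        if idx != len(heads) + 1:
            raise ValueError(f"line {lineno}: token ids must be consecutive from 1")
        head = int(cols[6])
        heads.append(head - 1 if head > 0 else -1)
        deprels.append(cols[7])
    flush()

    if expected_tokens is not None:
        for sid, tree in trees.items():
            if sid in expected_tokens and expected_tokens[sid] != len(tree):
                raise ValueError(
                    f"token count mismatch for sentence {sid!r}: "
                    f"parse has {len(tree)}, corpus has {expected_tokens[sid]}"
                )
    return trees


def lca_trigger(tree: DependencyTree, index_a: int, index_b: int) -> int:
    """Deepest node common to the root paths of both tokens.

    This is the uppermost node at the intersection of the two syntactic
    paths; the root is always common, so the result is well defined.
    """
    n = len(tree)
    for i in (index_a, index_b):
        if not (0 <= i < n):
            raise IndexError(f"token index {i} out of range for {n}-token tree")
    ancestors_a = set(tree.root_path(index_a))
    for node in tree.root_path(index_b):  # bottom-up: first hit is deepest
        if node in ancestors_a:
            return node
    raise AssertionError("unreachable: root is always a common ancestor")


def mention_head_token(mention: EntityMention) -> int:
    """Head token of a mention span: its last token (right-headed NPs)."""
    return mention.end_tok - 1


def extract_relations(
    sentence: Sentence,
    tree: DependencyTree,
    mentions: Sequence[EntityMention],
    effect_lexicon: Mapping[str, str],
) -> list[RelationCandidate]:
    """Candidates for every ordered (agent-type, target-type) mention pair.

    ``effect_lexicon`` maps effect-word stems to polarity classes (e.g.
    ``{"induc": "activation", "repress": "repression"}``). A pair yields a
    candidate iff the LCA token of the two mention heads is tagged VERB or
    its stem is in the lexicon; the polarity is the lexicon class of the
    trigger stem when present, else "unspecified".
    """
    if len(tree) != len(sentence.tokens):
        raise ValueError(
            f"tree/sentence token mismatch for {sentence.sent_id!r}: "
            f"{len(tree)} vs {len(sentence.tokens)}"
        )
    in_sent = [m for m in mentions if m.sent_id == sentence.sent_id]
    agents = [m for m in in_sent if m.entity_type in AGENT_TYPES]
    targets = [m for m in in_sent if m.entity_type in TARGET_TYPES]
    out: list[RelationCandidate] = []
    for agent in agents:
        for target in targets:
            if agent is target:
                continue
            lca = lca_trigger(tree, mention_head_token(agent), mention_head_token(target))
            tok = sentence.tokens[lca]
            trig_stem = tok.stem or porter_stem(tok.surface)
            if tok.pos != "VERB" and trig_stem not in effect_lexicon:
                continue
            out.append(
                RelationCandidate(
                    agent=agent,
                    target=target,
                    trigger_index=lca,
                    trigger_surface=tok.surface,
                    trigger_stem=trig_stem,
                    polarity=effect_lexicon.get(trig_stem, "unspecified"),
                )
            )
    return out


def read_effect_lexicon(path: str | Path) -> dict[str, str]:
    """Effect lexicon file: one entry per line, ``word<TAB>polarity`` or
    just ``word`` (polarity defaults to "unspecified"); words are stemmed."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        word = parts[0].strip()
        polarity = parts[1].strip() if len(parts) > 1 and parts[1].strip() else "unspecified"
        out[porter_stem(word)] = polarity
    return out
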