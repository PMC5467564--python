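"""Cross-document sentence linking.

Sentences about the same subject are linked across (and optionally within)
articles: every sentence pair is scored with the combined similarity
engine, pairs at or above a scaled-score threshold are kept, and each
sentence's links are additionally capped at its ``top_k`` best (a link
survives the cap if it is within top_k for at least one endpoint, which
preserves graph symmetry). The computation is an offline all-pairs pass;
adding one document updates the graph incrementally with a result
identical to a full rebuild.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core_text import Document
from .similarity import SimilarityConfig, combined_similarity

SentKey = tuple[str, str]  # (doc_id, sent_id)


@dataclass(frozen=True)
class LinkConfig:
    """Threshold is on the 0-5 scaled score; ``top_k`` caps links per
    sentence; ``include_intra`` also links sentences of the same document."""

    threshold: float = 3.5
    top_k: int = 10
    include_intra: bool = True
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 5.0):
            raise ValueError("threshold must lie in [0, 5]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class SentenceLink:
    a: SentKey  # canonical: a < b lexicographically
    b: SentKey
    score: float

    def __post_init__(self) -> None:
        if not (self.a < self.b):
            raise ValueError("link endpoints must be in canonical (lexicographic) order")

    @property
    def cross_document(self) -> bool:
        return self.a[0] != self.b[0]


def _canonical(x: SentKey, y: SentKey, score: float) -> SentenceLink:
    return SentenceLink(min(x, y), max(x, y), score)


@dataclass
class LinkGraph:
    """The navigable link graph plus its config snapshot.

    ``raw_links`` holds every pair at or above the threshold;
    ``links`` is the public view after the top_k cap. Keeping the raw list
    makes incremental updates exactly equivalent to a batch rebuild even
    after a save/load round-trip.
    """

    corpus_id: str
    config: LinkConfig
    raw_links: list[SentenceLink]
    sentence_keys: list[SentKey]

    @property
    def links(self) -> list[SentenceLink]:
        return _apply_top_k(self.raw_links, self.config.top_k)

    # -- persistence ------------------------------------------------------

    def to_json(self) -> str:
        sim = self.config.similarity
        payload = {
            "format_version": 1,
            "corpus_id": self.corpus_id,
            "config": {
                "threshold": self.config.threshold,
                "top_k": self.config.top_k,
                "include_intra": self.config.include_intra,
                "similarity": {
                    "stemming": sim.stemming,
                    "lowercase": sim.lowercase,
                    "stopwords": sorted(sim.stopwords),
                    "weight_vsm": sim.weight_vsm,
                    "weight_taxonomy": sim.weight_taxonomy,
                    "weight_embedding": sim.weight_embedding,
                },
            },
            "sentences": [list(k) for k in self.sentence_keys],
            "links": [
                {"a": {"doc": l.a[0], "sent": l.a[1]},
                 "b": {"doc": l.b[0], "sent": l.b[1]},
                 "score": l.score}
                for l in self.links
            ],
            "raw_links": [[*l.a, *l.b, l.score] for l in self.raw_links],
        }
        return json.dumps(payload, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "LinkGraph":
        payload = json.loads(text)
        cfg = payload["config"]
        sim = cfg["similarity"]
        config = LinkConfig(
            threshold=cfg["threshold"],
            top_k=cfg["top_k"],
            include_intra=cfg["include_intra"],
            similarity=SimilarityConfig(
                stemming=sim["stemming"],
                lowercase=sim["lowercase"],
                stopwords=frozenset(sim["stopwords"]),
                weight_vsm=sim["weight_vsm"],
                weight_taxonomy=sim["weight_taxonomy"],
                weight_embedding=sim["weight_embedding"],
            ),
        )
        raw = [
            SentenceLink((da, sa), (db, sb), score)
            for da, sa, db, sb, score in payload["raw_links"]
        ]
        keys = [tuple(k) for k in payload["sentences"]]
        return cls(payload["corpus_id"], config, raw, keys)

    @classmethod
    def load(cls, path: str | Path) -> "LinkGraph":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _apply_top_k(raw: Sequence[SentenceLink], top_k: int) -> list[SentenceLink]:
    """Keep links within the top_k best of at least one endpoint.

    Ranking at an endpoint is by descending score with canonical pair
    order breaking ties, so the result is deterministic.
    """
    per_endpoint: dict[SentKey, list[SentenceLink]] = {}
    for l in raw:
        per_endpoint.setdefault(l.a, []).append(l)
        per_endpoint.setdefault(l.b, []).append(l)
    keep: set[tuple[SentKey, SentKey]] = set()
    for key, ls in per_endpoint.items():
        ls_sorted = sorted(ls, key=lambda l: (-l.score, l.a, l.b))
        for l in ls_sorted[:top_k]:
            keep.add((l.a, l.b))
    return sorted(
        (l for l in raw if (l.a, l.b) in keep),
        key=lambda l: (l.a, l.b),
    )


def _sentence_keys(doc: Document) -> list[SentKey]:
    return [(doc.doc_id, s.sent_id) for s in doc.sentences]


def _score_pairs(
    pairs: Iterable[tuple[SentKey, str, SentKey, str]],
    config: LinkConfig,
) -> list[SentenceLink]:
    out = []
    for ka, ta, kb, tb in pairs:
        score = combined_similarity(ta, tb, config.similarity).scaled
        if score >= config.threshold:
            out.append(_canonical(ka, kb, score))
    return out


def build_links(
    corpus: Sequence[Document],
    config: LinkConfig | None = None,
    corpus_id: str = "corpus",
) -> LinkGraph:
    """Score every sentence pair of a preprocessed corpus and keep those at
    or above the threshold, then apply the per-sentence top_k cap."""
    if not corpus:
        raise ValueError("empty corpus")
    config = config or LinkConfig()
    items: list[tuple[SentKey, str]] = []
    for doc in corpus:
        for sent in doc.sentences:
            items.append(((doc.doc_id, sent.sent_id), doc.sentence_text(sent)))

    def gen():
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                (ka, ta), (kb, tb) = items[i], items[j]
                if not config.include_intra and ka[0] == kb[0]:
                    continue
                yield ka, ta, kb, tb

    raw = sorted(_score_pairs(gen(), config), key=lambda l: (l.a, l.b))
    return LinkGraph(corpus_id, config, raw, [k for k, _ in items])


def add_document(
    graph: LinkGraph,
    corpus: Sequence[Document],
    new_document: Document,
    config: LinkConfig | None = None,
) -> LinkGraph:
    """Incrementally integrate one preprocessed document.

    Only pairs touching the new document are scored; the merged result is
    identical to rebuilding from scratch on the enlarged corpus (existing
    pair scores are unchanged and the top_k cap is re-derived from the
    merged raw link list).
    """
    config = config or graph.config
    existing_docs = {k[0] for k in graph.sentence_keys}
    if new_document.doc_id in existing_docs:
        raise ValueError(f"duplicate doc_id {new_document.doc_id!r}")

    new_items = [
        ((new_document.doc_id, s.sent_id), new_document.sentence_text(s))
        for s in new_document.sentences
    ]
    old_items: list[tuple[SentKey, str]] = []
    by_id = {d.doc_id: d for d in corpus}
    for key in graph.sentence_keys:
        doc = by_id[key[0]]
        sent = next(s for s in doc.sentences if s.sent_id == key[1])
        old_items.append((key, doc.sentence_text(sent)))

    def gen():
        for ka, ta in old_items:
            for kb, tb in new_items:
                yield ka, ta, kb, tb
        if config.include_intra:
            for i in range(len(new_items)):
                for j in range(i + 1, len(new_items)):
                    (ka, ta), (kb, tb) = new_items[i], new_items[j]
                    yield ka, ta, kb, tb

    raw = sorted(graph.raw_links + _score_pairs(gen(), config), key=lambda l: (l.a, l.b))
    return LinkGraph(
        graph.corpus_id,
        config,
        raw,
        graph.sentence_keys + [k for k, _ in new_items],
    )


@dataclass
class NeighborList:
    """Ranked linked sentences of one sentence, split into the
    same-document and cross-document partitions."""

    same_document: list[tuple[SentKey, float]]
    cross_document: list[tuple[SentKey, float]]


def neighbors(graph: LinkGraph, doc_id: str, sent_id: str) -> NeighborList:
    """Linked sentences of (doc_id, sent_id), sorted by descending score
    (ties by canonical pair order); unknown sentences are an error."""
    key: SentKey = (doc_id, sent_id)
    if key not in set(graph.sentence_keys):
        raise KeyError(f"unknown sentence {key!r}")
    hits: list[tuple[SentKey, float, SentKey]] = []
    for l in graph.links:
        if l.a == key:
            hits.append((l.b, l.score, l.a))
        elif l.b == key:
            hits.append((l.a, l.score, l.b))
    hits.sort(key=lambda h: (-h[1], min(h[0], h[2]), max(h[0], h[2])))
    same = [(k, s) for k, s, _ in hits if k[0] == doc_id]
    cross = [(k, s) for k, s, _ in hits if k[0] != doc_id]
    return NeighborList(same, cross)
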