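"""Distant-learning disambiguation of ambiguous entity mentions.

Many surface terms map to several reference-database identifiers (a protein
name that is also a gene name, orthologs sharing a symbol ...). Rather than
requiring a hand-annotated corpus, the model is trained by distant
supervision: the curated database itself links documents to entity
identifiers, and a mention whose candidate set intersects its document's
linked entities in exactly one identifier is taken as a (noisy but usable)
labeled instance.

The classifier is a multinomial naive Bayes over bag-of-feature counts with
Laplace smoothing: context-window stems plus the entity types of co-mentions
in the sentence and the document. It is implemented here directly — training
is a handful of count tables — so the model is a small versioned JSON file
with byte-identical serialization for identical inputs.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_text import Document, Sentence
from .terminology import EntityMention, Matcher, annotate

MODEL_FORMAT_VERSION = 1
DEFAULT_WINDOW = 5
DEFAULT_ALPHA = 1.0


@dataclass(frozen=True)
class ReferenceLink:
    """A database-provided (document, entity) association used as ground truth."""
    doc_id: str
    entity_id: str


def read_links(path: str | Path) -> list[ReferenceLink]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"doc_id", "entity_id"} - set(df.columns)
    if missing:
        raise ValueError(f"links file missing columns: {sorted(missing)}")
    seen: set[tuple[str, str]] = set()
    out: list[ReferenceLink] = []
    for r in df.itertuples(index=False):
        key = (r.doc_id, r.entity_id)
        if key not in seen:
            seen.add(key)
            out.append(ReferenceLink(*key))
    return out


def extract_features(
    mention: EntityMention,
    sentence: Sentence,
    doc_mentions: Sequence[EntityMention],
    window: int = DEFAULT_WINDOW,
) -> Counter:
    """Bag of context features for one mention.

    Contains the stems of tokens within a +/- ``window`` token span around
    the mention (the mention's own tokens excluded), the entity types of
    the other mentions in the same sentence (prefixed ``sent_type=``) and
    the entity types present elsewhere in the document (``doc_type=``).
    Features carry no document or sentence identifiers, so renaming
    documents never changes a feature bag.
    """
    bag: Counter = Counter()
    lo = max(0, mention.start_tok - window)
    hi = min(len(sentence.tokens), mention.end_tok + window)
    for k in range(lo, hi):
        if mention.start_tok <= k < mention.end_tok:
            continue
        tok = sentence.tokens[k]
        if any(c.isalpha() for c in tok.surface):
            bag[tok.stem] += 1
    for other in doc_mentions:
        if other is mention:
            continue
        if other.sent_id == mention.sent_id:
            bag[f"sent_type={other.entity_type}"] += 1
        else:
            bag[f"doc_type={other.entity_type}"] += 1
    return bag


class DisambiguationModel:
    """Multinomial naive Bayes over feature bags, Laplace-smoothed.

    ``priors[c]`` is the class prior P(c); ``feature_counts[c][f]`` the
    training count of feature f in class c. Per-class likelihoods over the
    vocabulary sum to 1 after smoothing by construction of the multinomial
    estimate (count + alpha) / (total + alpha * |V|).
    """

    def __init__(
        self,
        class_counts: Mapping[str, int],
        feature_counts: Mapping[str, Mapping[str, int]],
        alpha: float = DEFAULT_ALPHA,
        window: int = DEFAULT_WINDOW,
    ):
        if alpha <= 0:
            raise ValueError("smoothing constant alpha must be > 0")
        self.alpha = float(alpha)
        self.window = int(window)
        self.class_counts = {c: int(n) for c, n in sorted(class_counts.items())}
        self.feature_counts = {
            c: {f: int(n) for f, n in sorted(fc.items())}
            for c, fc in sorted(feature_counts.items())
        }
        self.vocabulary = sorted({f for fc in self.feature_counts.values() for f in fc})
        total = sum(self.class_counts.values())
        self._log_prior = {c: math.log(n / total) for c, n in self.class_counts.items()}
        self._totals = {c: sum(fc.values()) for c, fc in self.feature_counts.items()}

    # -- scoring -----------------------------------------------------------

    def log_likelihood(self, entity_id: str, bag: Mapping[str, int]) -> float:
        """log P(bag | class) + log P(class), unseen classes -> -inf."""
        if entity_id not in self.class_counts:
            return -math.inf
        fc = self.feature_counts[entity_id]
        denom = self._totals[entity_id] + self.alpha * len(self.vocabulary)
        ll = self._log_prior[entity_id]
        for f, n in bag.items():
            if f not in self._vocab_set:
                continue  # out-of-vocabulary features carry no signal
            ll += n * math.log((fc.get(f, 0) + self.alpha) / denom)
        return ll

    @property
    def _vocab_set(self) -> set[str]:
        if not hasattr(self, "_vocab_cache"):
            self._vocab_cache = set(self.vocabulary)
        return self._vocab_cache

    def posterior(self, candidate_ids: Sequence[str], bag: Mapping[str, int]) -> dict[str, float]:
        """Posterior over ``candidate_ids`` normalized to sum to 1.

        Candidates never seen in training share the mass uniformly if no
        candidate was seen at all.
        """
        lls = {c: self.log_likelihood(c, bag) for c in candidate_ids}
        finite = {c: v for c, v in lls.items() if v > -math.inf}
        if not finite:
            u = 1.0 / len(candidate_ids)
            return {c: u for c in candidate_ids}
        mx = max(finite.values())
        ws = {c: math.exp(v - mx) for c, v in finite.items()}
        z = sum(ws.values())
        post = {c: 0.0 for c in candidate_ids}
        post.update({c: w / z for c, w in ws.items()})
        return post

    # -- persistence -------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "alpha": self.alpha,
            "window": self.window,
            "class_counts": self.class_counts,
            "feature_counts": self.feature_counts,
        }
        return json.dumps(payload, sort_keys=True, indent=None, separators=(",", ":"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "DisambiguationModel":
        payload = json.loads(text)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        return cls(
            payload["class_counts"],
            payload["feature_counts"],
            alpha=payload["alpha"],
            window=payload["window"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "DisambiguationModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _sentence_index(doc: Document) -> dict[str, Sentence]:
    return {s.sent_id: s for s in doc.sentences}


def training_instances(
    corpus: Sequence[Document],
    links: Sequence[ReferenceLink],
    matcher: Matcher,
    window: int = DEFAULT_WINDOW,
) -> list[tuple[str, Counter]]:
    """Distantly labeled (entity_id, feature bag) pairs.

    Only ambiguous mentions (>= 2 candidates) whose candidate set meets the
    document's linked entities in exactly one identifier are used; mentions
    made ambiguous by the links themselves (2+ linked candidates) are
    skipped to keep the distant-labeling assumption clean.
    """
    by_doc: dict[str, set[str]] = {}
    doc_ids = {d.doc_id for d in corpus}
    for link in links:
        if link.doc_id not in doc_ids:
            raise ValueError(f"link references unknown doc_id {link.doc_id!r}")
        by_doc.setdefault(link.doc_id, set()).add(link.entity_id)

    instances: list[tuple[str, Counter]] = []
    for doc in corpus:
        linked = by_doc.get(doc.doc_id, set())
        if not linked:
            continue
        mentions = annotate(doc, matcher)
        sents = _sentence_index(doc)
        for m in mentions:
            if len(m.candidate_ids) < 2:
                continue
            overlap = [c for c in m.candidate_ids if c in linked]
            if len(overlap) != 1:
                continue
            bag = extract_features(m, sents[m.sent_id], mentions, window)
            instances.append((overlap[0], bag))
    return instances


def train_distant(
    corpus: Sequence[Document],
    links: Sequence[ReferenceLink],
    matcher: Matcher,
    alpha: float = DEFAULT_ALPHA,
    window: int = DEFAULT_WINDOW,
) -> DisambiguationModel:
    """Train the naive-Bayes disambiguator from database links.

    Deterministic given (corpus, links, alpha, window): identical inputs
    serialize to byte-identical model files.
    """
    instances = training_instances(corpus, links, matcher, window)
    if not instances:
        raise ValueError("no ambiguous training instances derivable from the links")
    class_counts: Counter = Counter()
    feature_counts: dict[str, Counter] = {}
    for label, bag in instances:
        class_counts[label] += 1
        feature_counts.setdefault(label, Counter()).update(bag)
    return DisambiguationModel(class_counts, feature_counts, alpha=alpha, window=window)


def disambiguate(
    mention: EntityMention,
    model: DisambiguationModel,
    sentence: Sentence,
    doc_mentions: Sequence[EntityMention],
) -> tuple[str, float]:
    """Resolve a mention; returns (entity_id, score in [0, 1]).

    Single-candidate mentions bypass the model with score 1. Otherwise the
    argmax posterior restricted to the candidates is returned; ties and the
    all-candidates-unseen case fall back to the lexicographically smallest
    identifier, the latter flagged ``low_confidence``.
    """
    if len(mention.candidate_ids) == 1:
        mention.resolved_id = mention.candidate_ids[0]
        return mention.candidate_ids[0], 1.0
    bag = extract_features(mention, sentence, doc_mentions, model.window)
    post = model.posterior(mention.candidate_ids, bag)
    best_score = max(post.values())
    best = min(c for c, p in post.items() if p == best_score)  # lexicographic tie-break
    unseen = all(c not in model.class_counts for c in mention.candidate_ids)
    mention.resolved_id = best
    mention.low_confidence = unseen
    return best, best_score


def resolve_corpus(
    corpus: Sequence[Document],
    matcher: Matcher,
    model: DisambiguationModel,
) -> dict[str, list[EntityMention]]:
    """Annotate every document and fill ``resolved_id`` on all mentions."""
    out: dict[str, list[EntityMention]] = {}
    for doc in corpus:
        mentions = annotate(doc, matcher)
        sents = _sentence_index(doc)
        for m in mentions:
            if len(m.candidate_ids) > 1:
                disambiguate(m, model, sents[m.sent_id], mentions)
            else:
                m.resolved_id = m.candidate_ids[0]
        out[doc.doc_id] = mentions
    return out


def write_links(links: Iterable[ReferenceLink], path: str | Path) -> None:
    pd.DataFrame([{"doc_id": l.doc_id, "entity_id": l.entity_id} for l in links]).to_csv(
        path, sep="\t", index=False
    )
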