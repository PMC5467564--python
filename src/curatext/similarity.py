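"""Sentence-similarity engine and its evaluation harness.

Three word/sentence similarity signals are combined:

* **VSM cosine** — each sentence becomes a bag-of-words count vector after
  normalization (lower-casing, Porter stemming, optional stopword removal);
  similarity is the cosine of the two sparse vectors.
* **Taxonomy (Lin)** — word similarity from an is-a concept taxonomy with
  corpus frequencies: ``sim(c1, c2) = 2 IC(lcs) / (IC(c1) + IC(c2))`` with
  information content ``IC(c) = -log p(c)``, ``p`` from cumulative
  descendant frequencies; ambiguous words take the maximum over their
  concept pairs.
* **Embeddings** — cosine of dense word vectors, clamped to [0, 1].

The two word-level signals are lifted to sentences by symmetrized greedy
best-match alignment. Metric scores in [0, 1] are combined by a weighted
arithmetic mean and scaled to the 0-5 STS scale where 5 means "same
meaning" and 0 "unrelated". System output is evaluated against gold pairs
by Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_text import tokenize
from ._porter import stem as porter_stem

STS_MAX = 5.0


# ---------------------------------------------------------------------------
# sentence vectors and cosine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityConfig:
    """Normalization and combination settings.

    Weights are non-negative and apply to (cosine_vsm, taxonomy,
    embedding); a metric with zero weight is skipped entirely (so the
    taxonomy / vector resources are only needed when their weight is
    positive).
    """

    stemming: bool = True
    lowercase: bool = True
    stopwords: frozenset[str] = frozenset()
    weight_vsm: float = 1.0
    weight_taxonomy: float = 0.0
    weight_embedding: float = 0.0
    taxonomy: "Taxonomy | None" = None
    vectors: "WordVectors | None" = None

    def __post_init__(self) -> None:
        ws = (self.weight_vsm, self.weight_taxonomy, self.weight_embedding)
        if any(w < 0 for w in ws):
            raise ValueError("metric weights must be >= 0")
        if sum(ws) == 0:
            raise ValueError("at least one metric weight must be positive")
        if self.weight_taxonomy > 0 and self.taxonomy is None:
            raise ValueError("taxonomy weight > 0 requires a taxonomy")
        if self.weight_embedding > 0 and self.vectors is None:
            raise ValueError("embedding weight > 0 requires word vectors")


def _content_words(text: str, config: SimilarityConfig) -> list[str]:
    """Normalized content tokens: alphabetic tokens, lower-cased/stemmed per
    config, stopwords removed (stopword test on the lower-cased surface)."""
    words: list[str] = []
    for tok in tokenize(text):
        if not any(c.isalpha() for c in tok.surface):
            continue
        low = tok.surface.lower()
        if low in config.stopwords:
            continue
        if config.stemming:
            words.append(porter_stem(tok.surface))
        elif config.lowercase:
            words.append(low)
        else:
            words.append(tok.surface)
    return words


def vectorize(text: str, config: SimilarityConfig | None = None) -> dict[str, int]:
    """Bag-of-words count vector of a sentence (sparse map term -> count)."""
    config = config or SimilarityConfig()
    vec: dict[str, int] = {}
    for w in _content_words(text, config):
        vec[w] = vec.get(w, 0) + 1
    return vec


def cosine(v1: Mapping[str, int], v2: Mapping[str, int]) -> float:
    """Cosine of two sparse count vectors; 0 if either is empty."""
    if not v1 or not v2:
        return 0.0
    dot = sum(c * v2[k] for k, c in v1.items() if k in v2)
    n1 = math.sqrt(sum(c * c for c in v1.values()))
    n2 = math.sqrt(sum(c * c for c in v2.values()))
    return dot / (n1 * n2)


# ---------------------------------------------------------------------------
# taxonomy + Lin word similarity
# ---------------------------------------------------------------------------

class Taxonomy:
    """An is-a concept DAG (single root) with frequencies and a word map.

    ``p(c)`` is the cumulative frequency of c and all its descendants over
    the total, so ``p(root) = 1`` and ``IC(root) = 0``; IC never decreases
    from root to leaf along is-a chains.
    """

    def __init__(
        self,
        parents: Mapping[str, Sequence[str]],
        frequencies: Mapping[str, float],
        word_map: Mapping[str, Sequence[str]],
    ):
        self.parents = {c: list(ps) for c, ps in parents.items()}
        concepts = set(self.parents)
        for ps in self.parents.values():
            concepts.update(ps)
        self.concepts = sorted(concepts)
        roots = [c for c in self.concepts if not self.parents.get(c)]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have a single root, found {roots}")
        self.root = roots[0]
        self.frequencies = {c: float(frequencies.get(c, 0.0)) for c in self.concepts}
        self.word_map = {w: list(cs) for w, cs in word_map.items()}
        for w, cs in self.word_map.items():
            for c in cs:
                if c not in concepts:
                    raise ValueError(f"word {w!r} maps to unknown concept {c!r}")

        self._children: dict[str, list[str]] = {c: [] for c in self.concepts}
        for c, ps in self.parents.items():
            for p in ps:
                self._children[p].append(c)
        self._cumulative = {c: self._cum_freq(c, {}) for c in self.concepts}
        total = self._cumulative[self.root]
        if total <= 0:
            raise ValueError("total taxonomy frequency must be positive")
        self.ic = {
            c: (abs(-math.log(f / total)) if f > 0 else math.inf)
            for c, f in self._cumulative.items()
        }  # abs() normalizes -0.0 at the root

    def _cum_freq(self, c: str, memo: dict[str, float]) -> float:
        # DAG: a concept's descendant set is a set, not a multiset
        if c in memo:
            return memo[c]
        desc: set[str] = set()
        stack = [c]
        while stack:
            x = stack.pop()
            if x in desc:
                continue
            desc.add(x)
            stack.extend(self._children[x])
        memo[c] = sum(self.frequencies[d] for d in desc)
        return memo[c]

    def ancestors_or_self(self, c: str) -> set[str]:
        out: set[str] = set()
        stack = [c]
        while stack:
            x = stack.pop()
            if x in out:
                continue
            out.add(x)
            stack.extend(self.parents.get(x, ()))
        return out

    def contains_word(self, word: str) -> bool:
        return word in self.word_map

    # -- I/O (concept TSV + word-map TSV) ---------------------------------

    @classmethod
    def from_files(cls, concepts_path: str | Path, word_map_path: str | Path) -> "Taxonomy":
        cdf = pd.read_csv(concepts_path, sep="\t", dtype=str, keep_default_na=False)
        parents: dict[str, list[str]] = {}
        freqs: dict[str, float] = {}
        for r in cdf.itertuples(index=False):
            parents.setdefault(r.concept, [])
            if r.parent:
                parents[r.concept].append(r.parent)
            freqs[r.concept] = float(r.frequency)
        wdf = pd.read_csv(word_map_path, sep="\t", dtype=str, keep_default_na=False)
        word_map: dict[str, list[str]] = {}
        for r in wdf.itertuples(index=False):
            word_map.setdefault(r.word, []).append(r.concept)
        return cls(parents, freqs, word_map)

    def write(self, concepts_path: str | Path, word_map_path: str | Path) -> None:
        rows = []
        for c in self.concepts:
            ps = self.parents.get(c) or [""]
            for p in ps:
                rows.append({"concept": c, "parent": p, "frequency": self.frequencies[c]})
        pd.DataFrame(rows).to_csv(concepts_path, sep="\t", index=False)
        wrows = [
            {"word": w, "concept": c}
            for w in sorted(self.word_map)
            for c in self.word_map[w]
        ]
        pd.DataFrame(wrows).to_csv(word_map_path, sep="\t", index=False)


def lin_similarity(taxonomy: Taxonomy, w1: str, w2: str) -> float:
    """Lin word similarity: ``2 IC(lcs) / (IC(c1) + IC(c2))``.

    The lowest common subsumer in a DAG is the common ancestor-or-self with
    maximal IC. Ambiguous words take the maximum over their concept pairs.
    A word absent from the taxonomy scores 0 (out of vocabulary); a pair
    whose only common subsumer is the root scores 0 (IC(root) = 0).
    Identical non-root concepts score 1.
    """
    if not taxonomy.contains_word(w1) or not taxonomy.contains_word(w2):
        return 0.0
    best = 0.0
    for c1 in taxonomy.word_map[w1]:
        anc1 = taxonomy.ancestors_or_self(c1)
        for c2 in taxonomy.word_map[w2]:
            common = anc1 & taxonomy.ancestors_or_self(c2)
            ic_lcs = max(taxonomy.ic[c] for c in common)
            denom = taxonomy.ic[c1] + taxonomy.ic[c2]
            if denom <= 0 or math.isinf(denom):
                score = 1.0 if (c1 == c2 and math.isinf(taxonomy.ic[c1])) else 0.0
            else:
                score = 2.0 * ic_lcs / denom
            best = max(best, min(1.0, score))
    return best


# ---------------------------------------------------------------------------
# word embeddings
# ---------------------------------------------------------------------------

class WordVectors:
    """Dense word vectors of a fixed dimension (default 50)."""

    def __init__(self, vectors: Mapping[str, Sequence[float]], dim: int | None = None):
        self.vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        if not self.vectors:
            raise ValueError("empty vector set")
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(d[0] for d in dims)}")
        self.dim = next(iter(dims))[0]
        if dim is not None and self.dim != dim:
            raise ValueError(f"expected dimension {dim}, found {self.dim}")
        if self.dim <= 0:
            raise ValueError("vector dimension must be positive")

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    @classmethod
    def from_file(cls, path: str | Path) -> "WordVectors":
        """Text format: optional first line ``vocab_size d``, then
        ``word f1 ... fd`` per line; a row of the wrong width is an error."""
        vectors: dict[str, list[float]] = {}
        expected: int | None = None
        with open(path, encoding="utf-8") as fh:
            first = True
            for lineno, raw in enumerate(fh, 1):
                parts = raw.split()
                if not parts:
                    continue
                if first and len(parts) == 2 and all(p.lstrip("-").isdigit() for p in parts):
                    expected = int(parts[1])
                    first = False
                    continue
                first = False
                word, vals = parts[0], parts[1:]
                if expected is not None and len(vals) != expected:
                    raise ValueError(
                        f"line {lineno}: vector for {word!r} has {len(vals)} "
                        f"dimensions, expected {expected}"
                    )
                vectors[word] = [float(v) for v in vals]
        return cls(vectors, dim=expected)

    def write(self, path: str | Path, header: bool = True) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(f"{len(self.vectors)} {self.dim}\n")
            for w in sorted(self.vectors):
                vals = " ".join(format(x, ".6g") for x in self.vectors[w])
                fh.write(f"{w} {vals}\n")


def embedding_word_sim(vectors: WordVectors, w1: str, w2: str) -> float:
    """Cosine of the two word vectors clamped to [0, 1] (negative cosine
    carries no similarity signal); out-of-vocabulary words score 0."""
    if w1 not in vectors or w2 not in vectors:
        return 0.0
    a, b = vectors.vectors[w1], vectors.vectors[w2]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return max(0.0, min(1.0, float(np.dot(a, b) / (na * nb))))


# ---------------------------------------------------------------------------
# word-alignment aggregation and combination
# ---------------------------------------------------------------------------

def aligned_word_score(
    words1: Sequence[str],
    words2: Sequence[str],
    word_sim_fn: Callable[[str, str], float],
) -> float:
    """Symmetrized greedy best-match alignment score.

    Each word of one sentence is matched to its most similar word in the
    other; the directional score is the mean best-match similarity, and
    the result averages both directions. Either sentence empty -> 0.
    """
    if not words1 or not words2:
        return 0.0

    def directional(a: Sequence[str], b: Sequence[str]) -> float:
        return sum(max(word_sim_fn(w, v) for v in b) for w in a) / len(a)

    return 0.5 * (directional(words1, words2) + directional(words2, words1))


@dataclass
class SentencePairScore:
    metrics: dict[str, float]  # per-metric raw scores in [0, 1]
    weights: dict[str, float]
    combined: float  # weighted mean, in [0, 1]
    scaled: float  # 5 x combined, the STS scale

    def __post_init__(self) -> None:
        assert -1e-9 <= self.combined <= 1 + 1e-9
        assert -1e-9 <= self.scaled <= STS_MAX + 1e-9


def combined_similarity(
    text1: str,
    text2: str,
    config: SimilarityConfig | None = None,
) -> SentencePairScore:
    """Score a sentence pair with every enabled metric and combine.

    The combined score is the weight-normalized mean of the enabled raw
    metrics; the scaled score is 5x that, on the 0-5 STS scale. Identical
    sentences score 5 under any weighting.
    """
    config = config or SimilarityConfig()
    metrics: dict[str, float] = {}
    weights: dict[str, float] = {}
    if config.weight_vsm > 0:
        metrics["cosine_vsm"] = cosine(vectorize(text1, config), vectorize(text2, config))
        weights["cosine_vsm"] = config.weight_vsm
    if config.weight_taxonomy > 0:
        assert config.taxonomy is not None
        w1, w2 = _content_words(text1, config), _content_words(text2, config)
        metrics["taxonomy"] = aligned_word_score(
            w1, w2, lambda a, b: lin_similarity(config.taxonomy, a, b)
        )
        weights["taxonomy"] = config.weight_taxonomy
    if config.weight_embedding > 0:
        assert config.vectors is not None
        w1, w2 = _content_words(text1, config), _content_words(text2, config)
        metrics["embedding"] = aligned_word_score(
            w1, w2, lambda a, b: embedding_word_sim(config.vectors, a, b)
        )
        weights["embedding"] = config.weight_embedding
    wsum = sum(weights.values())
    combined = sum(weights[m] * metrics[m] for m in metrics) / wsum
    combined = min(1.0, max(0.0, combined))  # guard float overshoot
    return SentencePairScore(metrics, weights, combined, STS_MAX * combined)


# ---------------------------------------------------------------------------
# evaluation harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldPair:
    text1: str
    text2: str
    gold: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gold <= STS_MAX):
            raise ValueError(f"gold score {self.gold} outside [0, {STS_MAX}]")


def read_gold_pairs(path: str | Path) -> list[GoldPair]:
    df = pd.read_csv(path, sep="\t", dtype={"text1": str, "text2": str, "score": float},
                     keep_default_na=False)
    missing = {"text1", "text2", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"gold pairs file missing columns: {sorted(missing)}")
    return [GoldPair(r.text1, r.text2, float(r.score)) for r in df.itertuples(index=False)]


def write_gold_pairs(pairs: Iterable[GoldPair], path: str | Path) -> None:
    pd.DataFrame(
        [{"text1": p.text1, "text2": p.text2, "score": p.gold} for p in pairs]
    ).to_csv(path, sep="\t", index=False)


def pearson(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Product-moment correlation; zero variance in either input is an error."""
    if len(xs) != len(ys):
        raise ValueError("length mismatch")
    if len(xs) < 2:
        raise ValueError("need at least two points")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(xs, ys).statistic)


@dataclass
class StsReport:
    pearson_r: float
    n: int
    system_scores: list[float] = field(repr=False)
    gold_scores: list[float] = field(repr=False)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"system": self.system_scores, "gold": self.gold_scores}
        ).to_csv(path, sep="\t", index=False)


def evaluate_sts(gold_pairs: Sequence[GoldPair], config: SimilarityConfig | None = None) -> StsReport:
    """Score every pair and report the Pearson correlation with the gold."""
    if len(gold_pairs) < 2:
        raise ValueError("need at least two gold pairs")
    system = [combined_similarity(p.text1, p.text2, config).scaled for p in gold_pairs]
    gold = [p.gold for p in gold_pairs]
    return StsReport(pearson(system, gold), len(gold_pairs), system, gold)
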