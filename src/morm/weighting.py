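"""Corpus-derived edge weights: TF-IDF confidence, impact significance.

Edges extracted from a document corpus (abstracts, case reports, ...)
carry two weights.  *Confidence* scores how reliably two concepts
co-occur: for an unordered concept pair (u, v),

    tf(u, v)  = n(u, v)                  co-occurring document count
    idf(u, v) = log((N + 1) / (df + 1)) + 1
    w(u, v)   = tf · idf,    confidence = w / max_pairs w

where N is the corpus size and df the pair's document frequency (equal
to n here, since a pair occurs at most once per document).  The "+1"
terms smooth the ratio and floor idf at 1 so every observed pair gets a
positive weight even in single-document corpora; dividing by the
corpus-wide maximum maps weights into (0, 1] with the strongest pair at
exactly 1.  *Significance* scores how prominent the supporting
literature is: the mean impact factor of the documents containing the
pair, normalized by the maximum such mean, which makes it invariant to
rescaling all impact factors.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

from .model import BMKN, BMKNError, TypedEdge

Pair = tuple[str, str]


def _pair(u: str, v: str) -> Pair:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Document:
    """One corpus item: id, annotated concept ids, publication impact."""

    doc_id: str
    concept_ids: frozenset[str]
    impact_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.impact_factor < 0:
            raise BMKNError(f"impact factor of {self.doc_id!r} must be >= 0")


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)

    @property
    def n_documents(self) -> int:
        return len(self.documents)


def cooccurrence_counts(corpus: Corpus) -> dict[Pair, int]:
    """n(u, v): documents in which the unordered pair co-occurs."""
    if corpus.n_documents == 0:
        raise BMKNError("empty corpus")
    counts: Counter[Pair] = Counter()
    for doc in corpus.documents:
        for u, v in combinations(sorted(doc.concept_ids), 2):
            counts[_pair(u, v)] += 1
    return dict(counts)


def tfidf_confidence(corpus: Corpus, min_count: int = 1) -> dict[Pair, float]:
    """Max-normalized TF-IDF confidence for pairs with n >= min_count."""
    if min_count < 1:
        raise BMKNError("min_count must be >= 1")
    counts = cooccurrence_counts(corpus)
    n_docs = corpus.n_documents
    raw: dict[Pair, float] = {}
    for pair, n in counts.items():
        if n < min_count:
            continue
        idf = math.log((n_docs + 1) / (n + 1)) + 1.0
        raw[pair] = n * idf
    if not raw:
        raise BMKNError(f"no concept pair reaches min_count={min_count}")
    top = max(raw.values())
    return {pair: w / top for pair, w in raw.items()}


def significance_scores(corpus: Corpus) -> dict[Pair, float]:
    """Max-normalized mean impact factor of each pair's documents."""
    if corpus.n_documents == 0:
        raise BMKNError("empty corpus")
    if all(doc.impact_factor == 0 for doc in corpus.documents):
        raise BMKNError(
            "all impact factors are zero; significance undefined "
            "(fall back to default weights)"
        )
    sums: dict[Pair, float] = defaultdict(float)
    hits: dict[Pair, int] = defaultdict(int)
    for doc in corpus.documents:
        for u, v in combinations(sorted(doc.concept_ids), 2):
            pair = _pair(u, v)
            sums[pair] += doc.impact_factor
            hits[pair] += 1
    means = {pair: sums[pair] / hits[pair] for pair in sums}
    top = max(means.values())
    return {pair: m / top for pair, m in means.items()}


def extract_cooccurrence_edges(
    corpus: Corpus,
    bmkn: BMKN,
    rel: str,
    min_count: int = 1,
    cross_ontology_only: bool = True,
) -> list[TypedEdge]:
    """Materialize weighted edges (both directions) from co-occurrence.

    Each surviving pair yields two directed edges of type ``rel``
    carrying the pair's TF-IDF confidence and impact significance.  By
    default only cross-ontology pairs are emitted (inter-relationship
    extraction); same-ontology pairs are skipped.
    """
    for doc in corpus.documents:
        for cid in doc.concept_ids:
            if cid not in bmkn:
                raise BMKNError(
                    f"corpus concept {cid!r} (doc {doc.doc_id!r}) "
                    "not present in the network"
                )
    confidences = tfidf_confidence(corpus, min_count)
    try:
        significances = significance_scores(corpus)
    except BMKNError:
        significances = {}
    edges: list[TypedEdge] = []
    for (u, v), conf in sorted(confidences.items()):
        if cross_ontology_only and bmkn.ontology_of(u) == bmkn.ontology_of(v):
            continue
        sig = significances.get((u, v), 1.0)
        edges.append(TypedEdge(u, v, rel, conf, sig))
        edges.append(TypedEdge(v, u, rel, conf, sig))
    return edges


def attach_weights(
    bmkn: BMKN,
    weights: dict[Pair, tuple[float, float]],
    defaults: tuple[float, float] = (1.0, 1.0),
) -> BMKN:
    """Update existing edges with per-pair (confidence, significance).

    Both directions of a weighted pair are updated when present; edges
    not named keep their stored values, and edges carrying no values get
    the defaults.  Structured-source edges therefore stay at 1.0/1.0
    unless explicitly reweighted.
    """
    for (u, v) in weights:
        for endpoint in (u, v):
            if endpoint not in bmkn:
                raise BMKNError(f"weight key concept {endpoint!r} unknown")
    updated = bmkn.copy()
    for (u, v), (conf, sig) in weights.items():
        if not (0.0 <= conf <= 1.0 and 0.0 <= sig <= 1.0):
            raise BMKNError(f"weights for pair ({u!r}, {v!r}) out of [0, 1]")
        for a, b in ((u, v), (v, u)):
            if updated.graph.has_edge(a, b):
                for rel in list(updated.graph[a][b]):
                    updated.graph[a][b][rel]["confidence"] = conf
                    updated.graph[a][b][rel]["significance"] = sig
    for _, _, data in updated.graph.edges(data=True):
        data.setdefault("confidence", defaults[0])
        data.setdefault("significance", defaults[1])
    return updated
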