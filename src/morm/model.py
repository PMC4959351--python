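"""Core data model for a biomedical knowledge network (BMKN).

A BMKN is a directed graph ``G = (V, E, C, S)`` whose nodes are concepts
drawn from several ontologies (diseases, symptoms, genes, chemicals, ...)
and whose edges are typed relationships carrying two weights:

* ``confidence`` — a probability-like weight in [0, 1] that the
  relationship exists (corpus-derived edges get TF-IDF scores, ontology
  edges default to 1.0);
* ``significance`` — an importance weight in [0, 1] (corpus-derived edges
  get impact-factor scores, structured-source edges default to 1.0).

Every concept belongs to exactly one ontology (the total mapping ``Φ``),
and every edge has a relation type (the mapping ``Ψ``).  An edge whose
endpoints share an ontology is an *intra*-relationship; one that crosses
ontologies is an *inter*-relationship.  Expansion always follows stored
edge direction; inverse links exist only when a loader materializes them
as separate edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

INTRA = "intra"
INTER = "inter"
ANY = "any"


class BMKNError(ValueError):
    """Raised on violations of the knowledge-network contracts."""


@dataclass(frozen=True)
class Concept:
    """A node: stable id, human-readable label, owning ontology."""

    id: str
    label: str
    ontology: str

    def __post_init__(self) -> None:
        if not self.id:
            raise BMKNError("concept id must be non-empty")
        if not self.ontology:
            raise BMKNError("concept ontology must be non-empty")


@dataclass(frozen=True)
class RelationType:
    """A relation type token, optionally paired with a declared inverse.

    Examples: ``is_a``, ``has_symptom``, ``father_to_son`` (inverse
    ``son_to_father``).
    """

    name: str
    inverse: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise BMKNError("relation type name must be non-empty")


@dataclass(frozen=True)
class TypedEdge:
    """A directed, typed, weighted link between two concepts."""

    source: str
    target: str
    rel: str
    confidence: float = 1.0
    significance: float = 1.0

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise BMKNError(f"self-loop edge not allowed: {self.source!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise BMKNError(
                f"confidence {self.confidence} out of [0, 1] "
                f"on {self.source}->{self.target}"
            )
        if not (0.0 <= self.significance <= 1.0):
            raise BMKNError(
                f"significance {self.significance} out of [0, 1] "
                f"on {self.source}->{self.target}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.rel)


@dataclass
class BMKN:
    """The multi-ontology knowledge network.

    Backed by a :class:`networkx.MultiDiGraph` keyed by relation type, so
    parallel edges of different types between the same pair are allowed
    while exact ``(source, target, rel)`` duplicates are rejected.
    """

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    ontologies: set[str] = field(default_factory=set)

    # -- construction -------------------------------------------------

    def register_ontology(self, oid: str) -> "BMKN":
        if not oid:
            raise BMKNError("ontology id must be non-empty")
        if oid in self.ontologies:
            raise BMKNError(f"ontology {oid!r} already registered")
        self.ontologies.add(oid)
        return self

    def add_concept(self, concept: Concept) -> "BMKN":
        if concept.ontology not in self.ontologies:
            raise BMKNError(
                f"ontology {concept.ontology!r} of concept {concept.id!r} "
                "is not registered"
            )
        if concept.id in self.graph:
            raise BMKNError(f"duplicate concept id {concept.id!r}")
        self.graph.add_node(
            concept.id, label=concept.label, ontology=concept.ontology
        )
        return self

    def add_edge(self, edge: TypedEdge) -> "BMKN":
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.graph:
                raise BMKNError(f"edge endpoint {endpoint!r} unknown")
        if self.graph.has_edge(edge.source, edge.target, key=edge.rel):
            raise BMKNError(
                f"duplicate edge ({edge.source!r}, {edge.target!r}, {edge.rel!r})"
            )
        self.graph.add_edge(
            edge.source,
            edge.target,
            key=edge.rel,
            confidence=edge.confidence,
            significance=edge.significance,
        )
        return self

    # -- lookups ------------------------------------------------------

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.graph

    def concept(self, concept_id: str) -> Concept:
        try:
            data = self.graph.nodes[concept_id]
        except KeyError:
            raise BMKNError(f"unknown concept id {concept_id!r}") from None
        return Concept(concept_id, data["label"], data["ontology"])

    def ontology_of(self, concept_id: str) -> str:
        """Φ(v): the owning ontology of a concept."""
        return self.concept(concept_id).ontology

    def concept_ids(self, ontology: Optional[str] = None) -> set[str]:
        if ontology is None:
            return set(self.graph.nodes)
        return {
            v
            for v, data in self.graph.nodes(data=True)
            if data["ontology"] == ontology
        }

    def edges(self) -> Iterator[TypedEdge]:
        for u, v, rel, data in self.graph.edges(keys=True, data=True):
            yield TypedEdge(u, v, rel, data["confidence"], data["significance"])

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    # -- classification and traversal ---------------------------------

    def classify_edge(self, edge: TypedEdge) -> str:
        """Return ``"intra"`` iff Φ(source) = Φ(target), else ``"inter"``."""
        return INTRA if self.ontology_of(edge.source) == self.ontology_of(edge.target) else INTER

    def out_neighbors(
        self,
        node: str,
        relation_class: str = ANY,
        mask: "object | None" = None,
    ) -> set[str]:
        """Forward neighbors of ``node`` whose edge matches the class.

        ``mask`` is an optional :class:`morm.pruning.MaskSet` applied at
        traversal time; an edge is followed only if it passes.
        """
        if node not in self.graph:
            raise BMKNError(f"unknown concept id {node!r}")
        source_ont = self.graph.nodes[node]["ontology"]
        result: set[str] = set()
        for _, v, rel, data in self.graph.out_edges(node, keys=True, data=True):
            target_ont = self.graph.nodes[v]["ontology"]
            same = source_ont == target_ont
            if relation_class == INTRA and not same:
                continue
            if relation_class == INTER and same:
                continue
            if mask is not None and not mask.edge_passes(
                TypedEdge(node, v, rel, data["confidence"], data["significance"])
            ):
                continue
            result.add(v)
        return result

    # -- validation ---------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty iff consistent)."""
        report: list[str] = []
        for v, data in self.graph.nodes(data=True):
            ont = data.get("ontology")
            if ont not in self.ontologies:
                report.append(f"concept {v!r}: ontology {ont!r} not registered")
            if "label" not in data:
                report.append(f"concept {v!r}: missing label")
        for u, v, rel, data in self.graph.edges(keys=True, data=True):
            if u == v:
                report.append(f"edge ({u!r}, {v!r}, {rel!r}): self-loop")
            for weight in ("confidence", "significance"):
                value = data.get(weight)
                if value is None or not (0.0 <= value <= 1.0):
                    report.append(
                        f"edge ({u!r}, {v!r}, {rel!r}): {weight} {value!r} "
                        "out of [0, 1]"
                    )
        return report

    def copy(self) -> "BMKN":
        return BMKN(graph=self.graph.copy(), ontologies=set(self.ontologies))


def build_bmkn(
    ontologies: Iterable[str],
    concepts: Iterable[Concept],
    edges: Iterable[TypedEdge],
) -> BMKN:
    """Assemble a BMKN from iterables, enforcing all contracts."""
    net = BMKN()
    for oid in ontologies:
        net.register_ontology(oid)
    for concept in concepts:
        net.add_concept(concept)
    for edge in edges:
        net.add_edge(edge)
    return net
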