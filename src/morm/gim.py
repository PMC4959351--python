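"""General Inference Mechanism: set-theoretic relatedness expansion.

Relatedness around an *anchor concept* is computed as an indexed family
of concept sets ``iO_t^j`` — for each ontology ``t``, the concepts of
``t`` collected after ``j`` intra-relationship expansion steps and ``i``
inter-relationship expansion steps.  The family is defined by a
three-branch recursion over forward edge traversal:

* ``i = j``:  union of the two preceding cells, ``(i-1, j)`` and ``(i, j-1)``;
* ``i < j``:  one intra step applied to cell ``(i, j-1)``, unioned with it;
* ``i > j``:  inter steps into ``t`` from every other ontology's diagonal
  cell ``(i-1, i-1)``, unioned with cell ``(i-1, j)``.

The recursion grounds at the initial sets ``O_t^0``: for the anchor's
own ontology, the anchor's forward intra neighbors; for every other
ontology, the anchor's forward inter neighbors restricted to it.  The
anchor itself is excluded from every set.

The diagonal cell ``iO_t^i`` is the relatedness set after ``i`` full
steps; the union over ontologies of diagonal cells, with the edges the
network induces on them, forms the relatedness network (RN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import ANY, BMKN, INTER, INTRA, BMKNError, TypedEdge


@dataclass(frozen=True)
class AnchorSpec:
    """An expansion query: anchor concept, step count, optional mask."""

    anchor: str
    steps: int = 2
    mask: Optional[object] = None  # morm.pruning.MaskSet

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise BMKNError("steps must be >= 0")


# ---------------------------------------------------------------------
# Set operators (the ·R_intra and ·R_inter primitives)
# ---------------------------------------------------------------------


def intra_step(
    bmkn: BMKN,
    concept_set: set[str],
    ontology: str,
    mask: Optional[object] = None,
) -> set[str]:
    """One intra-relationship step: forward same-ontology neighbors.

    Returns only the neighbor set; callers compose the ``∪ previous``
    explicitly, which is how every identity of the recursion is written.
    """
    _check_membership(bmkn, concept_set, ontology)
    out: set[str] = set()
    for node in concept_set:
        out |= bmkn.out_neighbors(node, INTRA, mask)
    return out


def inter_step(
    bmkn: BMKN,
    concept_set: set[str],
    source_ontology: str,
    target_ontology: Optional[str] = None,
    mask: Optional[object] = None,
) -> set[str]:
    """One inter-relationship step: forward cross-ontology neighbors.

    With ``target_ontology`` given, the result is restricted to that
    ontology; with ``None`` all cross-ontology neighbors are returned.
    """
    _check_membership(bmkn, concept_set, source_ontology)
    out: set[str] = set()
    for node in concept_set:
        out |= bmkn.out_neighbors(node, INTER, mask)
    if target_ontology is not None:
        out = {v for v in out if bmkn.ontology_of(v) == target_ontology}
    return out


def _check_membership(bmkn: BMKN, concept_set: set[str], ontology: str) -> None:
    for node in concept_set:
        if bmkn.ontology_of(node) != ontology:
            raise BMKNError(
                f"concept {node!r} does not belong to ontology {ontology!r}"
            )


# ---------------------------------------------------------------------
# The recursion
# ---------------------------------------------------------------------


def initial_sets(bmkn: BMKN, anchor: AnchorSpec) -> dict[str, frozenset[str]]:
    """The grounding sets ``O_t^0`` for every registered ontology.

    Anchor ontology: forward intra neighbors of the anchor.  Every other
    ontology: forward inter neighbors of the anchor restricted to it.
    The anchor is excluded.
    """
    if anchor.anchor not in bmkn:
        raise BMKNError(f"unknown anchor {anchor.anchor!r}")
    anchor_ont = bmkn.ontology_of(anchor.anchor)
    singleton = {anchor.anchor}
    sets: dict[str, frozenset[str]] = {}
    for t in bmkn.ontologies:
        if t == anchor_ont:
            base = intra_step(bmkn, singleton, anchor_ont, anchor.mask)
        else:
            base = inter_step(bmkn, singleton, anchor_ont, t, anchor.mask)
        sets[t] = frozenset(base - singleton)
    return sets


@dataclass
class ExpansionState:
    """Memoized cells ``iO_t^j`` for one anchor query.

    Each cell is a pure function of ``(i, j, t)`` given the network and
    the mask, so memoization cannot change any result — only cost.
    """

    bmkn: BMKN
    anchor: AnchorSpec
    cells: dict[tuple[int, int, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._anchor_ont = self.bmkn.ontology_of(self.anchor.anchor)
        self._initial = initial_sets(self.bmkn, self.anchor)

    @property
    def anchor_ontology(self) -> str:
        return self._anchor_ont

    def cell(self, i: int, j: int, ontology: str) -> frozenset[str]:
        if i < 0 or j < 0:
            raise BMKNError("expansion indices must be >= 0")
        if ontology not in self.bmkn.ontologies:
            raise BMKNError(f"unknown ontology {ontology!r}")
        key = (i, j, ontology)
        if key in self.cells:
            return self.cells[key]

        mask = self.anchor.mask
        if i == 0 and j == 0:
            result = self._initial[ontology]
        elif i == j:
            result = self.cell(i - 1, j, ontology) | self.cell(i, j - 1, ontology)
        elif i < j:
            prev = self.cell(i, j - 1, ontology)
            result = intra_step(self.bmkn, set(prev), ontology, mask) | prev
        else:  # i > j
            result = frozenset(self.cell(i - 1, j, ontology))
            for k in self.bmkn.ontologies:
                if k == ontology:
                    continue
                diag = self.cell(i - 1, i - 1, k)
                result |= inter_step(self.bmkn, set(diag), k, ontology, mask)
        result = frozenset(result) - {self.anchor.anchor}
        self.cells[key] = result
        return result


def expand(bmkn: BMKN, anchor: AnchorSpec, i: int, j: int, ontology: str) -> frozenset[str]:
    """Compute the single cell ``iO_t^j`` (fresh memo per call)."""
    return ExpansionState(bmkn, anchor).cell(i, j, ontology)


# ---------------------------------------------------------------------
# Relatedness network assembly
# ---------------------------------------------------------------------


@dataclass
class RNNode:
    id: str
    label: str
    ontology: str
    first_i: int
    first_j: int


@dataclass
class RNEdge:
    source: str
    target: str
    rel: str
    confidence: float
    significance: float
    relation_class: str


@dataclass
class RelatednessNetwork:
    """Concepts collected around an anchor, with their induced links.

    ``nodes`` excludes the anchor (it is the query, recorded as
    ``anchor``); ``edges`` are all network edges among collected nodes
    or between the anchor and a collected node, mask-filtered.
    """

    anchor: str
    steps: int
    nodes: list[RNNode]
    edges: list[RNEdge]

    @property
    def node_ids(self) -> set[str]:
        return {n.id for n in self.nodes}

    def has_path(self, *chain: str) -> bool:
        """True iff consecutive chain members are linked by RN edges
        (either direction), through anchor or collected nodes."""
        present = self.node_ids | {self.anchor}
        links = {(e.source, e.target) for e in self.edges}
        links |= {(b, a) for a, b in links}
        for a, b in zip(chain, chain[1:]):
            if a not in present or b not in present or (a, b) not in links:
                return False
        return True


def relatedness_network(bmkn: BMKN, anchor: AnchorSpec) -> RelatednessNetwork:
    """Assemble the RN at ``anchor.steps`` full expansion steps."""
    state = ExpansionState(bmkn, anchor)
    s = anchor.steps

    # first-collection index: scan cells outward by (i + j, i, j)
    first_seen: dict[str, tuple[int, int]] = {}
    for total in range(0, 2 * s + 1):
        for i in range(0, min(total, s) + 1):
            j = total - i
            if j > s:
                continue
            for t in sorted(bmkn.ontologies):
                for node in state.cell(i, j, t):
                    first_seen.setdefault(node, (i, j))

    collected: set[str] = set()
    for t in bmkn.ontologies:
        collected |= state.cell(s, s, t)
    collected -= {anchor.anchor}

    nodes = [
        RNNode(
            id=v,
            label=bmkn.concept(v).label,
            ontology=bmkn.ontology_of(v),
            first_i=first_seen[v][0],
            first_j=first_seen[v][1],
        )
        for v in sorted(collected)
    ]

    keep = collected | {anchor.anchor}
    edges = []
    for edge in bmkn.edges():
        if edge.source in keep and edge.target in keep:
            if anchor.mask is not None and not anchor.mask.edge_passes(edge):
                continue
            edges.append(
                RNEdge(
                    edge.source,
                    edge.target,
                    edge.rel,
                    edge.confidence,
                    edge.significance,
                    bmkn.classify_edge(edge),
                )
            )
    edges.sort(key=lambda e: (e.source, e.target, e.rel))
    return RelatednessNetwork(anchor=anchor.anchor, steps=s, nodes=nodes, edges=edges)


def diagonal_profile(
    bmkn: BMKN, anchor: AnchorSpec, max_steps: int
) -> tuple[list[dict[str, frozenset[str]]], Optional[int]]:
    """Diagonal sets ``iO_t^i`` for i = 0..max_steps, plus the fixpoint.

    Returns ``(profile, fixpoint_step)`` where ``fixpoint_step`` is the
    first step at which no ontology's diagonal set grew (None if growth
    continues through ``max_steps``).  Supports choosing the step count
    for a given network.
    """
    if max_steps < 0:
        raise BMKNError("max_steps must be >= 0")
    state = ExpansionState(bmkn, anchor)
    profile: list[dict[str, frozenset[str]]] = []
    fixpoint: Optional[int] = None
    for i in range(max_steps + 1):
        step_sets = {t: state.cell(i, i, t) for t in bmkn.ontologies}
        if fixpoint is None and i > 0 and step_sets == profile[-1]:
            fixpoint = i
        if fixpoint is None and i == 0:
            # an isolated anchor is already at its fixpoint
            if all(not s for s in step_sets.values()):
                fixpoint = 0
        profile.append(step_sets)
    return profile, fixpoint
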