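"""Search-space reduction: link masks, the interesting set F(i), hubs.

A *link mask* is a triplet ``R(t, c, s)`` attached to a relation type:
``t`` is an include flag (0 blocks the type outright), ``c`` and ``s``
are confidence and significance thresholds.  An edge of a masked type is
followed only when ``t = 1`` and its confidence is strictly greater than
``c`` and its significance strictly greater than ``s``; comparisons are
strict, so boundary equality blocks.  When ``t = 0`` the thresholds are
irrelevant.  A mask set combines typed entries with an optional
wildcard ("rest"/"all") that covers every other type; types matched by
no entry pass.

The *interesting set* ``F(i) = iO_t^i − 0O_t^i`` removes from the full
relatedness set everything reachable by intra expansion alone, leaving
the concepts connected to the anchor only through cross-ontology paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .gim import AnchorSpec, ExpansionState
from .model import ANY, BMKN, BMKNError, TypedEdge

WILDCARDS = ("all", "rest")


@dataclass(frozen=True)
class Mask:
    """One ``R(t, c, s)`` triplet for a relation type (or the wildcard)."""

    rel: str
    include: int
    confidence: float = 0.0
    significance: float = 0.0

    def __post_init__(self) -> None:
        if self.include not in (0, 1):
            raise BMKNError(f"mask include flag must be 0 or 1, got {self.include}")
        for name, value in (("confidence", self.confidence), ("significance", self.significance)):
            if not (0.0 <= value <= 1.0):
                raise BMKNError(f"mask {name} threshold {value} out of [0, 1]")

    @property
    def is_wildcard(self) -> bool:
        return self.rel in WILDCARDS


@dataclass(frozen=True)
class MaskSet:
    """Ordered mask entries: typed first, at most one wildcard last."""

    entries: tuple[Mask, ...] = ()

    def __post_init__(self) -> None:
        typed = [m.rel for m in self.entries if not m.is_wildcard]
        if len(typed) != len(set(typed)):
            raise BMKNError("duplicate typed mask entries")
        if sum(m.is_wildcard for m in self.entries) > 1:
            raise BMKNError("at most one wildcard mask entry allowed")
        ordered = tuple(
            sorted(self.entries, key=lambda m: m.is_wildcard)
        )
        object.__setattr__(self, "entries", ordered)

    def match(self, rel: str) -> Optional[Mask]:
        for entry in self.entries:
            if entry.rel == rel or entry.is_wildcard:
                return entry
        return None

    def edge_passes(self, edge: TypedEdge) -> bool:
        """True iff the first matching entry admits the edge.

        Admission requires ``include = 1`` plus strictly-greater
        confidence and significance; no matching entry means pass.
        """
        entry = self.match(edge.rel)
        if entry is None:
            return True
        if entry.include == 0:
            return False
        return edge.confidence > entry.confidence and edge.significance > entry.significance


def parse_mask(spec: str) -> MaskSet:
    """Parse ``"rel:t:c:s,rel:t:c:s,..."`` into a :class:`MaskSet`.

    ``rest`` or ``all`` is the wildcard, e.g. ``"R1:0:0:0,rest:1:0.2:0.35"``.
    """
    entries = []
    for chunk in spec.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(":")
        if len(parts) != 4:
            raise BMKNError(f"malformed mask entry {chunk!r}: expected rel:t:c:s")
        rel, t_str, c_str, s_str = parts
        if not rel:
            raise BMKNError(f"malformed mask entry {chunk!r}: empty relation")
        try:
            t = int(t_str)
            c = float(c_str)
            s = float(s_str)
        except ValueError:
            raise BMKNError(f"malformed mask entry {chunk!r}: bad number") from None
        entries.append(Mask(rel, t, c, s))
    if not entries:
        raise BMKNError(f"empty mask specification {spec!r}")
    return MaskSet(tuple(entries))


@dataclass
class PruneSummary:
    kept: dict[str, int] = field(default_factory=dict)
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return sum(self.kept.values())

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def apply_masks(bmkn: BMKN, mask_set: MaskSet) -> tuple[BMKN, PruneSummary]:
    """Whole-graph pruning: keep exactly the passing edges.

    All concepts are retained; only edges are dropped.  Equivalent to
    traversal-time masking for every expansion cell.
    """
    pruned = BMKN()
    for oid in sorted(bmkn.ontologies):
        pruned.register_ontology(oid)
    for cid in bmkn.concept_ids():
        pruned.add_concept(bmkn.concept(cid))
    summary = PruneSummary()
    for edge in bmkn.edges():
        if mask_set.edge_passes(edge):
            pruned.add_edge(edge)
            summary.kept[edge.rel] = summary.kept.get(edge.rel, 0) + 1
        else:
            summary.removed[edge.rel] = summary.removed.get(edge.rel, 0) + 1
    return pruned, summary


def interesting_set(
    bmkn: BMKN, anchor: AnchorSpec, i: int, target_ontology: str
) -> frozenset[str]:
    """``F(i) = iO_t^i − 0O_t^i``: concepts reached only via inter paths."""
    if i < 0:
        raise BMKNError("step count must be >= 0")
    if target_ontology not in bmkn.ontologies:
        raise BMKNError(f"unknown ontology {target_ontology!r}")
    state = ExpansionState(bmkn, anchor)
    return state.cell(i, i, target_ontology) - state.cell(0, i, target_ontology)


def exclude_hubs(
    bmkn: BMKN,
    relation_class: str = ANY,
    max_degree: Optional[int] = None,
    top_percentile: Optional[float] = None,
) -> tuple[BMKN, list[str]]:
    """Remove high-degree concepts and their incident edges.

    Degree counts in- plus out-edges of the selected relation class.
    Exactly one of ``max_degree`` (absolute cutoff, degrees strictly
    above it are removed) or ``top_percentile`` (remove the nodes in the
    top given percent of the degree distribution) must be supplied —
    there is deliberately no default cutoff.
    """
    if (max_degree is None) == (top_percentile is None):
        raise BMKNError("supply exactly one of max_degree or top_percentile")
    if max_degree is not None and max_degree < 0:
        raise BMKNError("max_degree must be >= 0")

    degree: dict[str, int] = {cid: 0 for cid in bmkn.concept_ids()}
    for edge in bmkn.edges():
        if relation_class != ANY and bmkn.classify_edge(edge) != relation_class:
            continue
        degree[edge.source] += 1
        degree[edge.target] += 1

    if max_degree is not None:
        hubs = sorted(v for v, d in degree.items() if d > max_degree)
    else:
        if not (0.0 < top_percentile <= 100.0):
            raise BMKNError("top_percentile must be in (0, 100]")
        positive = sorted(
            (v for v, d in degree.items() if d > 0),
            key=lambda v: (-degree[v], v),
        )
        n_remove = int(round(len(positive) * top_percentile / 100.0))
        hubs = sorted(positive[:n_remove])

    pruned = bmkn.copy()
    pruned.graph.remove_nodes_from(hubs)
    return pruned, hubs
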