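"""Deliberately naive re-implementation of the expansion recursion.

Independent oracle for the memoized engine: no caching, no adjacency
index — every neighbor set is recomputed by scanning the full edge list.
Kept intentionally close to the printed three-branch recursion so that a
disagreement points at the engine, not the oracle.
"""

from __future__ import annotations

from morm.model import BMKN


def _edges(bmkn: BMKN, mask=None):
    for edge in bmkn.edges():
        if mask is None or mask.edge_passes(edge):
            yield edge


def naive_intra(bmkn: BMKN, concept_set, ontology, mask=None):
    out = set()
    for edge in _edges(bmkn, mask):
        if (
            edge.source in concept_set
            and bmkn.ontology_of(edge.source) == ontology
            and bmkn.ontology_of(edge.target) == ontology
        ):
            out.add(edge.target)
    return out


def naive_inter(bmkn: BMKN, concept_set, source_ontology, target_ontology, mask=None):
    out = set()
    for edge in _edges(bmkn, mask):
        if (
            edge.source in concept_set
            and bmkn.ontology_of(edge.source) == source_ontology
            and bmkn.ontology_of(edge.target) == target_ontology
        ):
            out.add(edge.target)
    return out


def naive_cell(bmkn: BMKN, anchor: str, i: int, j: int, ontology: str, mask=None):
    """Direct uncached evaluation of the cell iO_t^j."""
    anchor_ont = bmkn.ontology_of(anchor)
    if i == 0 and j == 0:
        if ontology == anchor_ont:
            base = naive_intra(bmkn, {anchor}, anchor_ont, mask)
        else:
            base = naive_inter(bmkn, {anchor}, anchor_ont, ontology, mask)
    elif i == j:
        base = naive_cell(bmkn, anchor, i - 1, j, ontology, mask) | naive_cell(
            bmkn, anchor, i, j - 1, ontology, mask
        )
    elif i < j:
        prev = naive_cell(bmkn, anchor, i, j - 1, ontology, mask)
        base = naive_intra(bmkn, prev, ontology, mask) | prev
    else:
        base = set(naive_cell(bmkn, anchor, i - 1, j, ontology, mask))
        for k in bmkn.ontologies:
            if k == ontology:
                continue
            diag = naive_cell(bmkn, anchor, i - 1, i - 1, k, mask)
            base |= naive_inter(bmkn, diag, k, ontology, mask)
    return base - {anchor}
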