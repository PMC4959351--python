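"""Synthetic inputs: the worked-example network, random multi-ontology
networks, planted-ground-truth networks for evaluation studies, and toy
corpora for weight computation.

The worked-example fixture is a two-ontology disease/symptom network
built to satisfy, exactly, every printed identity of the expansion
recursion (initial sets through F(2)) together with the misdiagnosis
chain Lupus → Painful Swollen Joint → Joint Swelling → Rheumatoid
Arthritis.  It is the package's primary regression oracle: each identity
was verified by hand-evaluating the recursion on the edge list before
the fixture was trusted.

Random networks emulate ontology structure as rooted trees ("is-a"-like
hierarchies, edges directed parent to child) with optional extra intra
edges, plus Bernoulli cross-ontology links.  All generation is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evaluation import ReferenceList
from .gim import AnchorSpec, ExpansionState
from .model import BMKN, BMKNError, Concept, TypedEdge, build_bmkn
from .weighting import Corpus, Document

INTRA_TREE_REL = "father_to_son"
INTRA_EXTRA_REL = "related_to"
INTER_REL = "associated_with"


# ---------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------

_FIG_LABELS = {
    "D0": "Lupus",
    "D11": "Rheumatoid Arthritis",
    "S2": "Painful Swollen Joint",
    "S3": "Joint Swelling",
}


def fig3_fixture() -> BMKN:
    """Two-ontology disease (D) / symptom (S) worked-example network.

    Anchor D0 ("Lupus").  Expansion from D0 reproduces:
    D0 intra-neighbors {D1, D2}; inter-neighbors {S1, S2};
    one intra step more gives {D3, D4} and {S3, S4, S5}; symptom-side
    inter edges lead back to diseases {D9, D10, D11, D12}; and
    F(2) = {D9, D10, D11, D12}.
    """
    d_ids = [f"D{k}" for k in [0, 1, 2, 3, 4, 9, 10, 11, 12]]
    s_ids = [f"S{k}" for k in range(1, 6)]
    concepts = [Concept(i, _FIG_LABELS.get(i, i), "D") for i in d_ids]
    concepts += [Concept(i, _FIG_LABELS.get(i, i), "S") for i in s_ids]
    intra_d = [("D0", "D1"), ("D0", "D2"), ("D1", "D3"), ("D2", "D4")]
    intra_s = [("S2", "S3"), ("S1", "S4"), ("S2", "S5")]
    inter_ds = [("D0", "S1"), ("D0", "S2"), ("D2", "S3")]
    inter_sd = [("S1", "D9"), ("S2", "D10"), ("S3", "D11"), ("S4", "D12")]
    edges = [TypedEdge(u, v, "is_a") for u, v in intra_d + intra_s]
    edges += [TypedEdge(u, v, "has_symptom") for u, v in inter_ds]
    edges += [TypedEdge(u, v, "symptom_of") for u, v in inter_sd]
    return build_bmkn(["D", "S"], concepts, edges)


# ---------------------------------------------------------------------
# Random networks
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape parameters for random multi-ontology networks.

    ``intra_extra_rate`` is the number of extra (non-tree) intra edges
    per concept; ``inter_rate`` the Bernoulli probability of a directed
    cross-ontology link per ordered concept pair.  Weight ranges are
    uniform sampling intervals; the degenerate default keeps every
    weight at 1.0.
    """

    seed: int
    n_ontologies: int = 3
    concepts_per_ontology: int = 15
    tree_branching: int = 3
    intra_extra_rate: float = 0.1
    inter_rate: float = 0.02
    confidence_range: tuple[float, float] = (1.0, 1.0)
    significance_range: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_ontologies < 1 or self.concepts_per_ontology < 1:
            raise BMKNError("ontology and concept counts must be >= 1")
        if self.tree_branching == 0 and self.concepts_per_ontology > 1:
            raise BMKNError("tree_branching 0 cannot host more than a root")
        if not (0.0 <= self.inter_rate <= 1.0):
            raise BMKNError("inter_rate must be in [0, 1]")
        if self.intra_extra_rate < 0:
            raise BMKNError("intra_extra_rate must be >= 0")
        for lo, hi in (self.confidence_range, self.significance_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise BMKNError("weight ranges must satisfy 0 <= lo <= hi <= 1")


def _draw_weight(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    lo, hi = lo_hi
    return lo if lo == hi else float(rng.uniform(lo, hi))


def random_bmkn(config: SyntheticConfig) -> BMKN:
    """Reproducible random network per the config (same seed, same graph)."""
    rng = np.random.default_rng(config.seed)
    net = BMKN()
    onts = [f"O{t}" for t in range(1, config.n_ontologies + 1)]
    for oid in onts:
        net.register_ontology(oid)
        for k in range(config.concepts_per_ontology):
            cid = f"{oid}_{k}"
            net.add_concept(Concept(cid, cid, oid))

    # rooted tree per ontology: each node attaches to a parent that
    # still has capacity under the branching limit
    for oid in onts:
        children: dict[int, int] = {0: 0}
        for k in range(1, config.concepts_per_ontology):
            capacity = [p for p, c in children.items() if c < config.tree_branching]
            parent = int(rng.choice(capacity))
            children[parent] += 1
            children[k] = 0
            net.add_edge(
                TypedEdge(
                    f"{oid}_{parent}",
                    f"{oid}_{k}",
                    INTRA_TREE_REL,
                    _draw_weight(rng, config.confidence_range),
                    _draw_weight(rng, config.significance_range),
                )
            )
        n_extra = int(round(config.intra_extra_rate * config.concepts_per_ontology))
        attempts = 0
        added = 0
        while added < n_extra and attempts < 50 * max(n_extra, 1):
            attempts += 1
            u, v = rng.integers(0, config.concepts_per_ontology, size=2)
            if u == v:
                continue
            su, sv = f"{oid}_{u}", f"{oid}_{v}"
            if net.graph.has_edge(su, sv, key=INTRA_EXTRA_REL):
                continue
            net.add_edge(
                TypedEdge(
                    su, sv, INTRA_EXTRA_REL,
                    _draw_weight(rng, config.confidence_range),
                    _draw_weight(rng, config.significance_range),
                )
            )
            added += 1

    for a in onts:
        for b in onts:
            if a == b:
                continue
            for u in range(config.concepts_per_ontology):
                hits = np.flatnonzero(
                    rng.random(config.concepts_per_ontology) < config.inter_rate
                )
                for v in hits:
                    net.add_edge(
                        TypedEdge(
                            f"{a}_{u}", f"{b}_{v}", INTER_REL,
                            _draw_weight(rng, config.confidence_range),
                            _draw_weight(rng, config.significance_range),
                        )
                    )
    return net


# ---------------------------------------------------------------------
# Planted ground truth
# ---------------------------------------------------------------------


def planted_truth_bmkn(
    config: SyntheticConfig,
    n_planted: int,
    seed: int,
    n_anchors: int = 1,
    n_near: int = 1,
) -> tuple[BMKN, list[ReferenceList]]:
    """A two-ontology network with known cross-ontology discoveries.

    Ontology ``O1`` plays the disease role, ``O2`` the mediator
    (symptom/gene) role.  For each anchor — an internal node of the
    disease tree — ``n_planted`` diseases at least three forward intra
    steps away are wired to share one dedicated mediator concept with
    the anchor (anchor → mediator → partner, both inter edges), so they
    are discoverable exactly through cross-ontology expansion.  The
    anchor's reference list records these partners plus ``n_near``
    diseases inside the radius-2 intra ball (discoverable from the
    hierarchy alone), mimicking reference lists that mix both kinds.
    """
    base = SyntheticConfig(
        seed=config.seed,
        n_ontologies=2,
        concepts_per_ontology=config.concepts_per_ontology,
        tree_branching=config.tree_branching,
        intra_extra_rate=config.intra_extra_rate,
        inter_rate=config.inter_rate,
        confidence_range=config.confidence_range,
        significance_range=config.significance_range,
    )
    net = random_bmkn(base)
    rng = np.random.default_rng(seed)
    disease_ont = "O1"
    diseases = sorted(net.concept_ids(disease_ont))

    internal = sorted(
        d for d in diseases if net.out_neighbors(d, relation_class="intra")
    )
    if len(internal) < n_anchors:
        raise BMKNError("not enough internal disease nodes for the anchors")
    anchors = [internal[k] for k in rng.choice(len(internal), n_anchors, replace=False)]

    references: list[ReferenceList] = []
    mediator_serial = 0
    for anchor in anchors:
        spec = AnchorSpec(anchor, steps=2)
        ball = set(ExpansionState(net, spec).cell(0, 2, disease_ont))
        far = sorted(set(diseases) - ball - {anchor})
        if len(far) < n_planted:
            raise BMKNError(
                f"anchor {anchor!r}: only {len(far)} diseases beyond the "
                f"intra ball, need {n_planted}"
            )
        planted = [far[k] for k in rng.choice(len(far), n_planted, replace=False)]
        for partner in planted:
            mediator = f"O2_planted_{mediator_serial}"
            mediator_serial += 1
            net.add_concept(Concept(mediator, mediator, "O2"))
            net.add_edge(TypedEdge(anchor, mediator, INTER_REL))
            net.add_edge(TypedEdge(mediator, partner, INTER_REL))
        near_pool = sorted(ball)
        near = [near_pool[k] for k in rng.choice(len(near_pool), min(n_near, len(near_pool)), replace=False)]
        references.append(
            ReferenceList(anchor, frozenset(planted) | frozenset(near))
        )
    return net, references


# ---------------------------------------------------------------------
# Toy corpora
# ---------------------------------------------------------------------


def synthetic_corpus(
    n_docs: int,
    concept_pool: Sequence[str],
    pair_bias: float,
    boosted_pairs: Optional[Sequence[tuple[str, str]]] = None,
    seed: int = 0,
) -> Corpus:
    """Documents over a concept pool with optionally boosted pairs.

    Each document draws 2–4 concepts uniformly from the pool; with
    probability ``pair_bias`` a randomly chosen boosted pair is injected
    into the document, raising its co-occurrence count.  Impact factors
    are log-normal (mu 1.0, sigma 0.5) — right-skewed, like journal
    impact factors.  Pure function of the arguments and the seed.
    """
    if not concept_pool:
        raise BMKNError("concept pool must be non-empty")
    if not (0.0 <= pair_bias <= 1.0):
        raise BMKNError("pair_bias must be in [0, 1]")
    pool = sorted(set(concept_pool))
    boosted = list(boosted_pairs or [])
    rng = np.random.default_rng(seed)
    documents = []
    for d in range(n_docs):
        size = int(rng.integers(2, 5))
        members = set(
            pool[k] for k in rng.choice(len(pool), min(size, len(pool)), replace=False)
        )
        if boosted and rng.random() < pair_bias:
            members |= set(boosted[int(rng.integers(0, len(boosted)))])
        documents.append(
            Document(
                doc_id=f"doc{d}",
                concept_ids=frozenset(members),
                impact_factor=float(rng.lognormal(mean=1.0, sigma=0.5)),
            )
        )
    return Corpus(documents)
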