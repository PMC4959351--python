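"""Readers and writers: OBO ontologies, TSV edge tables, JSONL corpora,
relatedness-network and BMKN exports, and the YAML-config loader that
assembles a full knowledge network from files.

All writers emit records in sorted order so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Union

import obonet
import yaml

from .gim import RelatednessNetwork, RNEdge, RNNode
from .model import BMKN, BMKNError, Concept, TypedEdge, build_bmkn
from .weighting import (
    Corpus,
    Document,
    extract_cooccurrence_edges,
)

PathLike = Union[str, Path]

EDGE_TABLE_COLUMNS = ("source", "target", "rel", "confidence", "significance")


# ---------------------------------------------------------------------
# OBO ontologies
# ---------------------------------------------------------------------


def read_obo(
    path: PathLike,
    ontology_id: Optional[str] = None,
    inverse_map: Optional[dict[str, str]] = None,
) -> tuple[str, list[Concept], list[TypedEdge]]:
    """Read an OBO flat file into concepts and typed intra edges.

    One concept per ``[Term]`` stanza (obsolete terms skipped); one edge
    per ``is_a`` and per ``relationship:`` line, typed by the tag.  When
    ``inverse_map`` declares an inverse name for a relation type (e.g.
    ``{"is_a": "father_to_son"}``), the reversed edge is materialized as
    a separate edge of that type.  The ontology id comes from the OBO
    header unless given explicitly.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    oid = ontology_id or graph.graph.get("ontology")
    if not oid:
        raise BMKNError(f"{path}: no ontology id in header; pass ontology_id")
    seen: set[str] = set()
    concepts: list[Concept] = []
    for term, data in graph.nodes(data=True):
        if term in seen:
            raise BMKNError(f"{path}: duplicate term id {term!r}")
        seen.add(term)
        concepts.append(Concept(term, data.get("name", term), oid))
    inverse_map = inverse_map or {}
    edges: list[TypedEdge] = []
    for u, v, rel in graph.edges(keys=True):
        edges.append(TypedEdge(u, v, rel))
        if rel in inverse_map:
            edges.append(TypedEdge(v, u, inverse_map[rel]))
    concepts.sort(key=lambda c: c.id)
    edges.sort(key=lambda e: e.key)
    return oid, concepts, edges


# ---------------------------------------------------------------------
# Edge tables (TSV)
# ---------------------------------------------------------------------


def read_edge_table(
    path: PathLike,
    default_confidence: float = 1.0,
    default_significance: float = 1.0,
) -> list[TypedEdge]:
    """Read a 3–5 column TSV (source, target, rel[, conf[, sig]]).

    A header row matching the canonical column names is skipped; missing
    weight columns are filled with the defaults.
    """
    rows: list[TypedEdge] = []
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and [c.lower() for c in row[:3]] == list(EDGE_TABLE_COLUMNS[:3]):
                continue
            if not 3 <= len(row) <= 5:
                raise BMKNError(
                    f"{path}:{lineno}: expected 3-5 columns, got {len(row)}"
                )
            source, target, rel = (c.strip() for c in row[:3])
            if not source or not target or not rel:
                raise BMKNError(f"{path}:{lineno}: empty identifier")
            try:
                conf = float(row[3]) if len(row) > 3 and row[3].strip() else default_confidence
                sig = float(row[4]) if len(row) > 4 and row[4].strip() else default_significance
            except ValueError:
                raise BMKNError(f"{path}:{lineno}: bad numeric weight") from None
            rows.append(TypedEdge(source, target, rel, conf, sig))
    return rows


def write_edge_table(edges: Iterable[TypedEdge], path: PathLike) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(EDGE_TABLE_COLUMNS)
        for edge in sorted(edges, key=lambda e: e.key):
            writer.writerow(
                [edge.source, edge.target, edge.rel,
                 repr(edge.confidence), repr(edge.significance)]
            )


# ---------------------------------------------------------------------
# Corpora (JSONL)
# ---------------------------------------------------------------------


def read_corpus_jsonl(path: PathLike) -> Corpus:
    """One document per line: {"doc_id", "concepts", "impact_factor"}."""
    documents: list[Document] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise BMKNError(f"{path}:{lineno}: bad JSON ({exc})") from None
            try:
                documents.append(
                    Document(
                        doc_id=str(record["doc_id"]),
                        concept_ids=frozenset(record["concepts"]),
                        impact_factor=float(record.get("impact_factor", 0.0)),
                    )
                )
            except KeyError as exc:
                raise BMKNError(f"{path}:{lineno}: missing field {exc}") from None
    return Corpus(documents)


def write_corpus_jsonl(corpus: Corpus, path: PathLike) -> None:
    with open(path, "w") as handle:
        for doc in corpus.documents:
            handle.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "concepts": sorted(doc.concept_ids),
                        "impact_factor": doc.impact_factor,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


# ---------------------------------------------------------------------
# Relatedness-network export
# ---------------------------------------------------------------------


def write_rn(rn: RelatednessNetwork, path: PathLike, format: str = "json") -> None:
    """Serialize an RN as JSON (nodes + edges) or a TSV edge list."""
    if format == "json":
        payload = {
            "anchor": rn.anchor,
            "steps": rn.steps,
            "nodes": [
                {
                    "id": n.id,
                    "label": n.label,
                    "ontology": n.ontology,
                    "first_i": n.first_i,
                    "first_j": n.first_j,
                }
                for n in sorted(rn.nodes, key=lambda n: n.id)
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "rel": e.rel,
                    "confidence": e.confidence,
                    "significance": e.significance,
                    "class": e.relation_class,
                }
                for e in sorted(rn.edges, key=lambda e: (e.source, e.target, e.rel))
            ],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")
    elif format == "tsv":
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["source", "target", "rel", "confidence", "significance", "class"]
            )
            for e in sorted(rn.edges, key=lambda e: (e.source, e.target, e.rel)):
                writer.writerow(
                    [e.source, e.target, e.rel,
                     repr(e.confidence), repr(e.significance), e.relation_class]
                )
    else:
        raise BMKNError(f"unknown RN format {format!r}")


def read_rn(path: PathLike) -> RelatednessNetwork:
    """Read back a JSON RN export (inverse of :func:`write_rn`)."""
    with open(path) as handle:
        payload = json.load(handle)
    nodes = [
        RNNode(n["id"], n["label"], n["ontology"], n["first_i"], n["first_j"])
        for n in payload["nodes"]
    ]
    edges = [
        RNEdge(
            e["source"], e["target"], e["rel"],
            e["confidence"], e["significance"], e["class"],
        )
        for e in payload["edges"]
    ]
    return RelatednessNetwork(
        anchor=payload["anchor"], steps=payload["steps"], nodes=nodes, edges=edges
    )


# ---------------------------------------------------------------------
# BMKN serialization
# ---------------------------------------------------------------------


def write_bmkn(bmkn: BMKN, path: PathLike) -> None:
    payload = {
        "ontologies": sorted(bmkn.ontologies),
        "concepts": [
            {"id": c.id, "label": c.label, "ontology": c.ontology}
            for c in sorted(
                (bmkn.concept(cid) for cid in bmkn.concept_ids()),
                key=lambda c: c.id,
            )
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "rel": e.rel,
                "confidence": e.confidence,
                "significance": e.significance,
            }
            for e in sorted(bmkn.edges(), key=lambda e: e.key)
        ],
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_bmkn(path: PathLike) -> BMKN:
    with open(path) as handle:
        payload = json.load(handle)
    return build_bmkn(
        payload["ontologies"],
        (Concept(c["id"], c["label"], c["ontology"]) for c in payload["concepts"]),
        (
            TypedEdge(
                e["source"], e["target"], e["rel"],
                e["confidence"], e["significance"],
            )
            for e in payload["edges"]
        ),
    )


# ---------------------------------------------------------------------
# Config-driven assembly
# ---------------------------------------------------------------------


def load_bmkn(config: Union[PathLike, dict]) -> BMKN:
    """Assemble a validated BMKN from a YAML config (or parsed dict).

    Config schema::

        ontologies:
          - {path: do.obo, id: DO, inverse_map: {is_a: father_to_son}}
        edge_tables:
          - {path: links.tsv, default_confidence: 1.0, default_significance: 1.0}
        corpus:
          {path: docs.jsonl, rel: co_occurs_with, min_count: 1}

    Edge-table and corpus edges must reference loaded concepts; the
    corpus contributes inter edges weighted by TF-IDF confidence and
    impact-factor significance.
    """
    if not isinstance(config, dict):
        base = Path(config).parent
        with open(config) as handle:
            config = yaml.safe_load(handle)
    else:
        base = Path(".")

    def _resolve(p: PathLike) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    net = BMKN()
    for entry in config.get("ontologies", []):
        oid, concepts, edges = read_obo(
            _resolve(entry["path"]),
            ontology_id=entry.get("id"),
            inverse_map=entry.get("inverse_map"),
        )
        net.register_ontology(oid)
        for concept in concepts:
            net.add_concept(concept)
        for edge in edges:
            net.add_edge(edge)

    for entry in config.get("edge_tables", []):
        rows = read_edge_table(
            _resolve(entry["path"]),
            default_confidence=entry.get("default_confidence", 1.0),
            default_significance=entry.get("default_significance", 1.0),
        )
        for edge in rows:
            for endpoint in (edge.source, edge.target):
                if endpoint not in net:
                    raise BMKNError(
                        f"{entry['path']}: edge references unknown concept "
                        f"{endpoint!r}"
                    )
            net.add_edge(edge)

    corpus_cfg = config.get("corpus")
    if corpus_cfg:
        corpus = read_corpus_jsonl(_resolve(corpus_cfg["path"]))
        edges = extract_cooccurrence_edges(
            corpus,
            net,
            rel=corpus_cfg.get("rel", "co_occurs_with"),
            min_count=corpus_cfg.get("min_count", 1),
        )
        for edge in edges:
            net.add_edge(edge)

    violations = net.validate()
    if violations:
        raise BMKNError("invalid network: " + "; ".join(violations))
    return net
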