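"""Annotation/method/weight filtering and subset-restricted topology statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .associations import AssociationTable, components_of_term, neighbors
from .hierarchy import AnnotationSet, Hierarchy
from .metagraph import MetaGraph

__all__ = [
    "DegreeHistogram",
    "filter_by_term",
    "unannotated_components",
    "filter_edges_by_method",
    "filter_edges_by_weight",
    "degree_distribution",
    "repositioning_candidates",
]


@dataclass
class DegreeHistogram:
    """Degree -> node count, optionally restricted to one node kind."""

    counts: dict[int, int] = field(default_factory=dict)
    restricted_kind: str | None = None

    def total_nodes(self) -> int:
        return sum(self.counts.values())


def filter_by_term(
    g: MetaGraph, h: Hierarchy, a: AnnotationSet, term_id: str
) -> set[str]:
    """Graph nodes annotated under a term's branch (annotation-based node
    filtering, e.g. marking the drug targets associated with one disease)."""
    branch = {c.casefold() for c in components_of_term(h, a, term_id, True)}
    return {
        nid
        for nid, node in g.nodes.items()
        if node.kind == a.component_kind and nid.casefold() in branch
    }


def unannotated_components(
    g: MetaGraph, h: Hierarchy, a: AnnotationSet, kind: str
) -> set[str]:
    """Nodes of a kind appearing in no term's cumulative component set
    (genes without disease/GO annotation, drugs without ATC class)."""
    annotated = {c.casefold() for c in a.all_components()}
    a.validate(h)
    return {
        nid
        for nid, node in g.nodes.items()
        if node.kind == kind and nid.casefold() not in annotated
    }


def filter_edges_by_method(g: MetaGraph, keep: Iterable[str]) -> MetaGraph:
    """Keep edges carrying at least one retained method tag (any-match);
    nodes are untouched."""
    keep = set(keep)
    out = g.copy()
    out.edges = {k: e for k, e in out.edges.items() if e.methods & keep}
    return out


def filter_edges_by_weight(g: MetaGraph, w_min: float) -> MetaGraph:
    """Keep edges with weight >= w_min; unweighted edges count as weight 1."""
    out = g.copy()
    out.edges = {
        k: e
        for k, e in out.edges.items()
        if (e.weight if e.weight is not None else 1.0) >= w_min
    }
    return out


def degree_distribution(g: MetaGraph, kind: str | None = None) -> DegreeHistogram:
    """Degree histogram over the flat view, restricted to one node kind.

    Degrees count all incident visible edges, including those to nodes
    outside the restricted kind (a drug's degree is its number of targets).
    """
    flat = g.flat_view()
    degrees: dict[str, int] = {nid: 0 for nid in flat.nodes}
    for e in flat.edges.values():
        degrees[e.u] += 1
        degrees[e.v] += 1
    counts: dict[int, int] = {}
    for nid, d in degrees.items():
        if kind is not None and flat.nodes[nid].kind != kind:
            continue
        counts[d] = counts.get(d, 0) + 1
    return DegreeHistogram(counts, restricted_kind=kind)


def repositioning_candidates(
    g: MetaGraph,
    h: Hierarchy,
    a: AnnotationSet,
    term_id: str,
    drug_target: AssociationTable,
) -> set[str]:
    """Drug-repositioning shortlist for a disease term.

    Filters the drug-target network down to the genes associated with the
    disease, then collects the drugs adjacent to the surviving genes — the
    assumption being that a drug whose targets are disease-associated may
    treat the disease.
    """
    disease_genes = filter_by_term(g, h, a, term_id)
    partners = neighbors(drug_target, disease_genes, side="right")
    graph_drugs = {
        nid.casefold(): nid for nid, n in g.nodes.items() if n.kind == "drug"
    }
    out = set()
    for drug, _method in partners:
        hit = graph_drugs.get(drug.casefold())
        if hit is not None:
            out.add(hit)
    return out
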