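"""Network transformations: bipartite and co-membership projections, metanode
correlation edges, and the factory for the 11 network types.

All derived networks start from the meta-network, in which each requested
disease/therapy term is a metanode embedding the genes/drugs annotated under
its branch.  The transformations then either turn metanodes into regular term
nodes linked to their former members (bipartite), project shared membership
onto component-component edges (co-metanode), or summarize pairs of metanodes
by their member overlap or by cross-member association records.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping

from .associations import AssociationTable
from .hierarchy import AnnotationSet, Hierarchy
from .metagraph import (
    DragDropMode,
    Edge,
    MetaGraph,
    MetaGraphError,
    MetaNode,
    Node,
    add_metanode,
)

__all__ = [
    "NetworkType",
    "bipartite_transform",
    "co_metanode_transform",
    "shared_component_edges",
    "interaction_based_edges",
    "derive_network",
]


class NetworkType(str, Enum):
    """The meta-network and the 10 network types derived from it."""

    META = "meta"
    DISEASE_DISEASE = "disease_disease"
    THERAPY_THERAPY = "therapy_therapy"
    DISEASE_THERAPY = "disease_therapy"
    DISEASE_GENE = "disease_gene"
    THERAPY_DRUG = "therapy_drug"
    CO_DISEASE_GENE = "co_disease_gene"
    CO_THERAPY_DRUG = "co_therapy_drug"
    DISEASE_GENE_DRUG = "disease_gene_drug"
    THERAPY_DRUG_GENE = "therapy_drug_gene"
    DISEASE_GENE_DRUG_THERAPY = "disease_gene_drug_therapy"


#: node kinds each network type may contain (outputs are subsets: a term with
#: no annotated drugs contributes no drug nodes)
TYPE_KINDS: dict[NetworkType, frozenset[str]] = {
    NetworkType.META: frozenset({"disease", "therapy", "gene", "drug"}),
    NetworkType.DISEASE_DISEASE: frozenset({"disease"}),
    NetworkType.THERAPY_THERAPY: frozenset({"therapy"}),
    NetworkType.DISEASE_THERAPY: frozenset({"disease", "therapy"}),
    NetworkType.DISEASE_GENE: frozenset({"disease", "gene"}),
    NetworkType.THERAPY_DRUG: frozenset({"therapy", "drug"}),
    NetworkType.CO_DISEASE_GENE: frozenset({"gene"}),
    NetworkType.CO_THERAPY_DRUG: frozenset({"drug"}),
    NetworkType.DISEASE_GENE_DRUG: frozenset({"disease", "gene", "drug"}),
    NetworkType.THERAPY_DRUG_GENE: frozenset({"therapy", "drug", "gene"}),
    NetworkType.DISEASE_GENE_DRUG_THERAPY: frozenset(
        {"disease", "therapy", "gene", "drug"}
    ),
}

_BIPARTITE_EDGE_KIND = {"therapy": "therapy_drug"}  # everything else: disease_gene


def _member_edge_kind(meta_kind: str) -> str:
    return _BIPARTITE_EDGE_KIND.get(meta_kind, "disease_gene")


def _require_metanodes(g: MetaGraph, metas: Iterable[str]) -> list[str]:
    out = []
    for mid in metas:
        g._require_metanode(mid)  # raises for non-metanodes
        out.append(mid)
    return sorted(set(out))


def bipartite_transform(g: MetaGraph, metas: Iterable[str]) -> MetaGraph:
    """Replace metanodes by regular term nodes linked to their members.

    Each metanode becomes an ordinary node of its kind, with one edge
    (disease_gene or therapy_drug) to each former component member.  Nested
    metanodes are transformed recursively; a component links to its innermost
    containing term only and no term-term edges are emitted, keeping the
    result bipartite.  Other nodes and edges are untouched.
    """
    out = g.copy()
    targets = _require_metanodes(out, metas)
    # include nested metanodes
    queue = list(targets)
    all_targets: set[str] = set()
    while queue:
        mid = queue.pop()
        if mid in all_targets:
            continue
        all_targets.add(mid)
        for member in out._require_metanode(mid).members:
            if isinstance(out.nodes[member], MetaNode):
                queue.append(member)
    links: list[tuple[str, str, str]] = []
    for mid in sorted(all_targets):
        meta = out._require_metanode(mid)
        kind = _member_edge_kind(meta.kind)
        for member in sorted(meta.members):
            if not isinstance(out.nodes[member], MetaNode):
                links.append((mid, member, kind))
    for mid in sorted(all_targets):
        meta = out._require_metanode(mid)
        out.nodes[mid] = Node(meta.id, meta.kind, dict(meta.properties))
    for mid, member, kind in links:
        out.add_edge(mid, member, edge_kind=kind)
    return out


def co_metanode_transform(g: MetaGraph, metas: Iterable[str]) -> MetaGraph:
    """Project shared membership onto component-component edges.

    The listed metanodes (and their nested metanodes) are removed; every
    unordered pair of a metanode's flattened members gains a co_membership
    edge whose weight counts how many of the listed metanodes contain the
    pair.
    """
    out = g.copy()
    targets = _require_metanodes(out, metas)
    pair_counts: dict[tuple[str, str], int] = {}
    to_remove: set[str] = set()
    for mid in targets:
        to_remove.add(mid)
        to_remove |= {
            m for m in out.membership_closure(mid) if isinstance(out.nodes[m], MetaNode)
        }
        flat = sorted(out.flattened_members(mid))
        for u, v in combinations(flat, 2):
            pair_counts[(u, v)] = pair_counts.get((u, v), 0) + 1
    for mid in sorted(to_remove):
        out.remove_node(mid)
    for (u, v), count in sorted(pair_counts.items()):
        out.add_edge(u, v, edge_kind="co_membership", weight=float(count))
    return out


def shared_component_edges(
    g: MetaGraph, metas: Iterable[str], weight_mode: str = "count"
) -> list[Edge]:
    """Metanode-metanode edges weighted by flattened member overlap.

    ``weight_mode="count"`` uses the raw intersection size;
    ``"jaccard"`` normalizes by the union size.  Pairs with empty
    intersection yield no edge.
    """
    if weight_mode not in ("count", "jaccard"):
        raise MetaGraphError(f"unknown weight mode {weight_mode!r}")
    targets = _require_metanodes(g, metas)
    flat = {mid: g.flattened_members(mid) for mid in targets}
    edges: list[Edge] = []
    for m1, m2 in combinations(targets, 2):
        overlap = flat[m1] & flat[m2]
        if not overlap:
            continue
        if weight_mode == "jaccard":
            weight = len(overlap) / len(flat[m1] | flat[m2])
        else:
            weight = float(len(overlap))
        edges.append(Edge(m1, m2, "shared_component", weight, {"shared_components"}))
    return edges


def interaction_based_edges(
    g: MetaGraph,
    metas: Iterable[str],
    table: AssociationTable,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> list[Edge]:
    """Metanode-metanode edges weighted by cross-member association records.

    For each metanode pair, the weight counts the records of *table*
    (gene_gene interactions or drug_target associations) linking a member of
    one to a member of the other; a record internal to the shared members of
    both contributes nothing.  Restrict to specific *pairs* if given.
    """
    if table.kind not in ("gene_gene", "drug_target"):
        raise MetaGraphError(
            f"interaction-based correlation needs gene_gene or drug_target, "
            f"got {table.kind!r}"
        )
    targets = _require_metanodes(g, metas)
    flat = {
        mid: {c.casefold() for c in g.flattened_members(mid)} for mid in targets
    }
    if pairs is None:
        candidate_pairs = list(combinations(targets, 2))
    else:
        candidate_pairs = [tuple(sorted(p)) for p in pairs]
    edges: list[Edge] = []
    for m1, m2 in sorted(set(candidate_pairs)):
        count = 0
        for left, right, _ in table.records:
            lf, rf = left.casefold(), right.casefold()
            if lf == rf:
                continue
            across = (lf in flat[m1] and rf in flat[m2]) or (
                lf in flat[m2] and rf in flat[m1]
            )
            if across:
                count += 1
        if count:
            edges.append(
                Edge(m1, m2, "shared_component", float(count), {table.kind})
            )
    return edges


# -- network factory ------------------------------------------------------


@dataclass
class _Layers:
    h_d: Hierarchy
    h_t: Hierarchy
    a_d: AnnotationSet
    a_t: AnnotationSet
    tables: Mapping[str, AssociationTable]
    disease_terms: list[str]
    therapy_terms: list[str]

    def table(self, kind: str, network_type: NetworkType) -> AssociationTable:
        try:
            return self.tables[kind]
        except KeyError:
            raise MetaGraphError(
                f"network type {network_type.value!r} requires the {kind!r} table"
            ) from None


def _build_meta(
    layers: _Layers,
    diseases: bool = True,
    therapies: bool = True,
    cross_edges: bool = False,
) -> MetaGraph:
    g = MetaGraph()
    if diseases:
        for t in sorted(layers.disease_terms):
            add_metanode(g, layers.h_d, layers.a_d, t, DragDropMode.ALL_COMPONENTS)
    if therapies:
        for t in sorted(layers.therapy_terms):
            add_metanode(g, layers.h_t, layers.a_t, t, DragDropMode.ALL_COMPONENTS)
    if cross_edges:
        by_kind: dict[str, dict[str, str]] = {}
        for nid, node in g.nodes.items():
            if not isinstance(node, MetaNode):
                by_kind.setdefault(node.kind, {})[nid.casefold()] = nid
        roles = {
            "drug_target": ("drug_target", "drug", "gene"),
            "gene_gene": ("interaction", "gene", "gene"),
        }
        for kind, (edge_kind, left_kind, right_kind) in roles.items():
            table = layers.tables.get(kind)
            if table is None:
                continue
            for left, right, method in sorted(table.records):
                u = by_kind.get(left_kind, {}).get(left.casefold())
                v = by_kind.get(right_kind, {}).get(right.casefold())
                if u is not None and v is not None and u != v:
                    g.add_edge(u, v, edge_kind=edge_kind, methods={method})
    return g


def _collapsed_correlation(
    layers: _Layers, which: str, network_type: NetworkType, weight_mode: str
) -> MetaGraph:
    g = _build_meta(layers, diseases=which == "disease", therapies=which == "therapy")
    metas = sorted(g.metanodes())
    edges = shared_component_edges(g, metas, weight_mode=weight_mode)
    out = MetaGraph()
    for mid in metas:
        meta = g._require_metanode(mid)
        out.add_node(Node(meta.id, meta.kind, dict(meta.properties)))
    for e in edges:
        out.add_edge(e.u, e.v, e.edge_kind, e.weight, e.methods)
    return out


def derive_network(
    h_d: Hierarchy,
    h_t: Hierarchy,
    a_d: AnnotationSet,
    a_t: AnnotationSet,
    tables: Mapping[str, AssociationTable],
    disease_terms: Iterable[str],
    therapy_terms: Iterable[str],
    network_type: NetworkType | str,
    weight_mode: str = "count",
) -> MetaGraph:
    """Construct one of the 11 network types from the hierarchy and
    association layers.

    ``disease_terms`` / ``therapy_terms`` select the metanodes of the
    meta-network; every other type is derived from it by the documented
    operator chain (bipartite/co-metanode transforms plus drug-target joins).
    ``weight_mode`` applies to shared-component correlation edges.
    """
    network_type = NetworkType(network_type)
    layers = _Layers(
        h_d,
        h_t,
        a_d,
        a_t,
        tables,
        [h_d.resolve(t) for t in disease_terms],
        [h_t.resolve(t) for t in therapy_terms],
    )

    if network_type is NetworkType.META:
        return _build_meta(layers, cross_edges=True)

    if network_type is NetworkType.DISEASE_DISEASE:
        return _collapsed_correlation(layers, "disease", network_type, weight_mode)

    if network_type is NetworkType.THERAPY_THERAPY:
        return _collapsed_correlation(layers, "therapy", network_type, weight_mode)

    if network_type is NetworkType.DISEASE_THERAPY:
        table = layers.table("drug_target", network_type)
        g = _build_meta(layers)
        disease_metas = sorted(layers.disease_terms)
        therapy_metas = sorted(layers.therapy_terms)
        pairs = [(d, t) for d in disease_metas for t in therapy_metas]
        edges = interaction_based_edges(g, disease_metas + therapy_metas, table, pairs)
        out = MetaGraph()
        for mid in disease_metas + therapy_metas:
            meta = g._require_metanode(mid)
            out.add_node(Node(meta.id, meta.kind, dict(meta.properties)))
        for e in edges:
            out.add_edge(e.u, e.v, e.edge_kind, e.weight, e.methods)
        return out

    if network_type is NetworkType.DISEASE_GENE:
        g = _build_meta(layers, therapies=False)
        return bipartite_transform(g, sorted(g.metanodes()))

    if network_type is NetworkType.THERAPY_DRUG:
        g = _build_meta(layers, diseases=False)
        return bipartite_transform(g, sorted(g.metanodes()))

    if network_type is NetworkType.CO_DISEASE_GENE:
        g = _build_meta(layers, therapies=False)
        return co_metanode_transform(g, sorted(g.metanodes()))

    if network_type is NetworkType.CO_THERAPY_DRUG:
        g = _build_meta(layers, diseases=False)
        return co_metanode_transform(g, sorted(g.metanodes()))

    if network_type is NetworkType.DISEASE_GENE_DRUG:
        table = layers.table("drug_target", network_type)
        g = derive_network(
            h_d, h_t, a_d, a_t, tables, layers.disease_terms, [], NetworkType.DISEASE_GENE
        )
        _join_drug_targets(g, table, query_genes=True)
        return g

    if network_type is NetworkType.THERAPY_DRUG_GENE:
        table = layers.table("drug_target", network_type)
        g = derive_network(
            h_d, h_t, a_d, a_t, tables, [], layers.therapy_terms, NetworkType.THERAPY_DRUG
        )
        _join_drug_targets(g, table, query_drugs=True)
        return g

    if network_type is NetworkType.DISEASE_GENE_DRUG_THERAPY:
        table = layers.table("drug_target", network_type)
        g = _build_meta(layers)
        g = bipartite_transform(g, sorted(g.metanodes()))
        _join_drug_targets(g, table, query_genes=True, query_drugs=True)
        return g

    raise MetaGraphError(f"unhandled network type {network_type!r}")  # pragma: no cover


def _join_drug_targets(
    g: MetaGraph,
    table: AssociationTable,
    query_genes: bool = False,
    query_drugs: bool = False,
) -> None:
    """Join drug-target records onto a graph in place.

    ``query_genes`` adds the drugs targeting the graph's gene nodes
    (Fig.-style disease-gene-drug join); ``query_drugs`` adds the targets of
    the graph's drug nodes.  New nodes are created as needed and every
    matched record becomes a drug_target edge.
    """
    genes = {nid for nid, n in g.nodes.items() if n.kind == "gene"}
    drugs = {nid for nid, n in g.nodes.items() if n.kind == "drug"}
    gene_index = {x.casefold(): x for x in genes}
    drug_index = {x.casefold(): x for x in drugs}
    for left, right, method in sorted(table.records):
        drug_hit = left.casefold() in drug_index
        gene_hit = right.casefold() in gene_index
        if (query_genes and gene_hit) or (query_drugs and drug_hit):
            drug_id = drug_index.setdefault(left.casefold(), left)
            gene_id = gene_index.setdefault(right.casefold(), right)
            if drug_id not in g.nodes:
                g.add_node(Node(drug_id, "drug"))
            if gene_id not in g.nodes:
                g.add_node(Node(gene_id, "gene"))
            g.add_edge(drug_id, gene_id, edge_kind="drug_target", methods={method})
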