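"""The metagraph model: typed nodes, nestable metanodes, provenance-tagged edges.

A metanode is a node that contains other nodes (its members) and can be
*expanded* (members visible) or *collapsed* (members hidden, external
adjacency summarized by meta-edges).  Here metanodes represent disease or
therapy terms containing the genes/drugs annotated under them; membership may
be nested (a disease term containing a sub-term metanode) and components may
belong to several metanodes at once, but never transitively to themselves.

The graph always stores the fully expanded edge set; :meth:`MetaGraph.flat_view`
derives the currently visible graph from the collapse states, so collapsing
then expanding is an identity by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .associations import components_of_term
from .hierarchy import AnnotationSet, Hierarchy

__all__ = [
    "NODE_KINDS",
    "EDGE_KINDS",
    "MetaGraphError",
    "DragDropMode",
    "Node",
    "MetaNode",
    "Edge",
    "MetaGraph",
    "add_metanode",
    "set_metanode_state",
    "select_same_properties",
]

NODE_KINDS = ("gene", "drug", "disease", "therapy")
EDGE_KINDS = (
    "interaction",
    "drug_target",
    "disease_gene",
    "therapy_drug",
    "shared_component",
    "co_membership",
)
_VISUAL_KEYS = ("shape", "color", "size")


class MetaGraphError(ValueError):
    pass


class DragDropMode(str, Enum):
    """The four metanode-creation options.

    Two axes: restrict members to components already in the graph
    (``existing_*``) or create missing component nodes (``all_*``); and embed
    sub-terms as nested metanodes (``*_with_subterms``) or flatten the branch
    into one member set.
    """

    ALL_COMPONENTS = "all_components"
    EXISTING_COMPONENTS_ONLY = "existing_components_only"
    ALL_WITH_SUBTERMS = "all_with_subterms"
    EXISTING_WITH_SUBTERMS = "existing_with_subterms"


@dataclass
class Node:
    id: str
    kind: str
    properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise MetaGraphError(f"unknown node kind {self.kind!r}")


@dataclass
class MetaNode(Node):
    members: set[str] = field(default_factory=set)
    state: str = "expanded"
    origin_term: str | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.state not in ("expanded", "collapsed"):
            raise MetaGraphError(f"unknown metanode state {self.state!r}")


@dataclass
class Edge:
    """An undirected typed edge; endpoints stored as a sorted pair."""

    u: str
    v: str
    edge_kind: str = "interaction"
    weight: float | None = None
    methods: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise MetaGraphError(f"self-loop on {self.u!r} not allowed")
        if self.edge_kind not in EDGE_KINDS:
            raise MetaGraphError(f"unknown edge kind {self.edge_kind!r}")
        if self.weight is not None and self.weight < 0:
            raise MetaGraphError("edge weight must be non-negative")
        if self.v < self.u:
            self.u, self.v = self.v, self.u
        self.methods = set(self.methods)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.u, self.v, self.edge_kind)


class MetaGraph:
    """Container for nodes, metanodes and typed edges.

    At most one edge exists per (endpoint pair, edge kind); re-adding merges
    method tags.  Membership acyclicity is asserted after every mutation.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, Node] = {}
        self.edges: dict[tuple[str, str, str], Edge] = {}

    # -- nodes ------------------------------------------------------------

    def add_node(self, node: Node) -> Node:
        existing = self.nodes.get(node.id)
        if existing is not None:
            if existing.kind != node.kind:
                raise MetaGraphError(
                    f"node {node.id!r} already present with kind {existing.kind!r}"
                )
            return existing
        self.nodes[node.id] = node
        if isinstance(node, MetaNode):
            self._assert_membership_acyclic()
        return node

    def remove_node(self, node_id: str) -> None:
        if node_id not in self.nodes:
            raise MetaGraphError(f"unknown node {node_id!r}")
        del self.nodes[node_id]
        self.edges = {k: e for k, e in self.edges.items() if node_id not in (e.u, e.v)}
        for m in self.metanodes().values():
            m.members.discard(node_id)

    def metanodes(self) -> dict[str, "MetaNode"]:
        return {i: n for i, n in self.nodes.items() if isinstance(n, MetaNode)}

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    # -- edges ------------------------------------------------------------

    def add_edge(
        self,
        u: str,
        v: str,
        edge_kind: str = "interaction",
        weight: float | None = None,
        methods: Iterable[str] = (),
    ) -> Edge:
        for endpoint in (u, v):
            if endpoint not in self.nodes:
                raise MetaGraphError(f"edge endpoint {endpoint!r} not in graph")
        edge = Edge(u, v, edge_kind, weight, set(methods))
        existing = self.edges.get(edge.key)
        if existing is not None:
            existing.methods |= edge.methods
            if weight is not None:
                existing.weight = weight
            return existing
        self.edges[edge.key] = edge
        return edge

    def incident_edges(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges.values() if node_id in (e.u, e.v)]

    # -- membership -------------------------------------------------------

    def set_members(self, metanode_id: str, members: Iterable[str]) -> None:
        meta = self._require_metanode(metanode_id)
        missing = [m for m in members if m not in self.nodes]
        if missing:
            raise MetaGraphError(f"members not in graph: {missing!r}")
        meta.members = set(members)
        self._assert_membership_acyclic()

    def flattened_members(self, metanode_id: str) -> frozenset[str]:
        """Component (non-metanode) members, descending through nesting."""
        meta = self._require_metanode(metanode_id)
        out: set[str] = set()
        stack = list(meta.members)
        while stack:
            mid = stack.pop()
            node = self.nodes[mid]
            if isinstance(node, MetaNode):
                stack.extend(node.members)
            else:
                out.add(mid)
        return frozenset(out)

    def membership_closure(self, metanode_id: str) -> frozenset[str]:
        """All member ids reachable through nesting, metanodes included."""
        meta = self._require_metanode(metanode_id)
        out: set[str] = set()
        stack = list(meta.members)
        while stack:
            mid = stack.pop()
            if mid in out:
                continue
            out.add(mid)
            node = self.nodes[mid]
            if isinstance(node, MetaNode):
                stack.extend(node.members)
        return frozenset(out)

    def _require_metanode(self, metanode_id: str) -> MetaNode:
        node = self.nodes.get(metanode_id)
        if not isinstance(node, MetaNode):
            raise MetaGraphError(f"{metanode_id!r} is not a metanode in this graph")
        return node

    def _assert_membership_acyclic(self) -> None:
        metas = self.metanodes()
        colors: dict[str, int] = {}

        def visit(mid: str, trail: list[str]) -> None:
            colors[mid] = 1
            trail.append(mid)
            for member in metas[mid].members:
                if member in metas:
                    if colors.get(member) == 1:
                        raise MetaGraphError(
                            f"metanode membership cycle through {member!r}"
                        )
                    if colors.get(member) != 2:
                        visit(member, trail)
            colors[mid] = 2
            trail.pop()

        for mid in metas:
            if colors.get(mid) is None:
                visit(mid, [])

    # -- flat view --------------------------------------------------------

    def _representative(self, node_id: str) -> str:
        """Visible stand-in for a node: itself, or the collapsed metanode
        hiding it.  With overlapping collapsed containers the smallest id
        wins, deterministically."""
        containers: dict[str, set[str]] = {}
        for mid, meta in self.metanodes().items():
            for member in meta.members:
                containers.setdefault(member, set()).add(mid)

        def hidden(nid: str, seen: frozenset[str]) -> bool:
            for mid in containers.get(nid, ()):
                if mid in seen:
                    continue
                if self._require_metanode(mid).state == "collapsed":
                    return True
                if hidden(mid, seen | {mid}):
                    return True
            return False

        if not hidden(node_id, frozenset()):
            return node_id
        # climb to the outermost collapsed container that is itself visible
        candidates = []
        stack = [(node_id, frozenset())]
        while stack:
            nid, seen = stack.pop()
            for mid in containers.get(nid, ()):
                if mid in seen:
                    continue
                meta = self._require_metanode(mid)
                if meta.state == "collapsed" and not hidden(mid, frozenset()):
                    candidates.append(mid)
                stack.append((mid, seen | {mid}))
        if not candidates:  # pragma: no cover - collapsed chain always tops out
            return node_id
        return min(candidates)

    def flat_view(self) -> "MetaGraph":
        """The visible graph given current collapse states.

        Members of collapsed metanodes are hidden; each edge from a hidden
        member to an external visible node becomes (part of) a meta-edge whose
        weight is the number of member edges it summarizes and whose method
        tags are their union.
        """
        reps = {nid: self._representative(nid) for nid in self.nodes}
        flat = MetaGraph()
        for nid, node in self.nodes.items():
            if reps[nid] == nid:
                flat.nodes[nid] = node
        merged: dict[tuple[str, str, str], Edge] = {}
        for edge in sorted(self.edges.values(), key=lambda e: e.key):
            ru, rv = reps[edge.u], reps[edge.v]
            if ru == rv:
                continue
            if (ru, rv) == (edge.u, edge.v):
                new = Edge(ru, rv, edge.edge_kind, edge.weight, set(edge.methods))
                merged[new.key] = new
            else:
                new = Edge(ru, rv, edge.edge_kind, None, set(edge.methods))
                prior = merged.get(new.key)
                if prior is None:
                    new.weight = 1.0
                    merged[new.key] = new
                else:
                    prior.weight = (prior.weight or 0.0) + 1.0
                    prior.methods |= new.methods
        flat.edges = merged
        return flat

    # -- utilities --------------------------------------------------------

    def copy(self) -> "MetaGraph":
        out = MetaGraph()
        for nid, node in self.nodes.items():
            if isinstance(node, MetaNode):
                out.nodes[nid] = MetaNode(
                    node.id,
                    node.kind,
                    dict(node.properties),
                    set(node.members),
                    node.state,
                    node.origin_term,
                )
            else:
                out.nodes[nid] = Node(node.id, node.kind, dict(node.properties))
        for key, edge in self.edges.items():
            out.edges[key] = Edge(
                edge.u, edge.v, edge.edge_kind, edge.weight, set(edge.methods)
            )
        return out

    def node_kinds(self) -> set[str]:
        return {n.kind for n in self.nodes.values()}

    def legend(self) -> dict[str, str]:
        """One exemplar node id per kind present (the legend's data)."""
        out: dict[str, str] = {}
        for nid in sorted(self.nodes):
            out.setdefault(self.nodes[nid].kind, nid)
        return out


# -- operations -----------------------------------------------------------


def _metanode_kind(hierarchy_kind: str, component_kind: str) -> str:
    # GO-style "function" terms become modules of their component kind
    if hierarchy_kind in ("disease", "therapy"):
        return hierarchy_kind
    return component_kind


def add_metanode(
    g: MetaGraph,
    h: Hierarchy,
    a: AnnotationSet,
    term_id: str,
    mode: DragDropMode | str = DragDropMode.ALL_COMPONENTS,
    recursive: bool = False,
) -> str:
    """Create a metanode for a hierarchy term (the drag&drop operation).

    ``all_*`` modes create any missing component nodes; ``existing_*`` modes
    intersect the branch components with nodes already in the graph (an empty
    result still creates the metanode, with a warning).  ``*_with_subterms``
    modes nest one metanode per child term holding at least one member, with
    each component placed in its deepest containing term only; set
    ``recursive=True`` to nest through every hierarchy level.
    """
    mode = DragDropMode(mode)
    canonical = h.resolve(term_id)
    existing_only = mode in (
        DragDropMode.EXISTING_COMPONENTS_ONLY,
        DragDropMode.EXISTING_WITH_SUBTERMS,
    )
    with_subterms = mode in (
        DragDropMode.ALL_WITH_SUBTERMS,
        DragDropMode.EXISTING_WITH_SUBTERMS,
    )
    kind = _metanode_kind(h.kind, a.component_kind)

    # fold ids only within the component kind: a disease term "D1" must not
    # capture a drug named "d1"
    graph_index = {
        nid.casefold(): nid
        for nid, node in g.nodes.items()
        if node.kind == a.component_kind and not isinstance(node, MetaNode)
    }

    def admit(components: frozenset[str]) -> set[str]:
        if existing_only:
            return {
                graph_index[c.casefold()]
                for c in components
                if c.casefold() in graph_index
            }
        out = set()
        for c in components:
            nid = graph_index.get(c.casefold())
            if nid is None:
                node = g.add_node(Node(c, a.component_kind))
                graph_index[c.casefold()] = c
                nid = c
            out.add(nid)
        return out

    def build(tid: str, nest: bool) -> str:
        if tid in g.nodes:
            raise MetaGraphError(f"node id {tid!r} already in graph")
        branch = admit(components_of_term(h, a, tid, include_descendants=True))
        members: set[str] = set()
        if nest:
            claimed: set[str] = set()
            for kid in sorted(h.children(tid)):
                kid_branch = admit(components_of_term(h, a, kid, include_descendants=True))
                if not kid_branch:
                    continue
                child_id = build(kid, recursive)
                members.add(child_id)
                claimed |= g.flattened_members(child_id)
            members |= branch - claimed
        else:
            members = branch
        meta = MetaNode(tid, kind, {}, set(), "expanded", tid)
        g.add_node(meta)
        g.set_members(tid, members)
        return tid

    mid = build(canonical, with_subterms)
    if existing_only and not g.flattened_members(mid):
        warnings.warn(
            f"metanode {mid!r} has no members present in the graph", stacklevel=2
        )
    return mid


def set_metanode_state(g: MetaGraph, metanode_id: str, state: str) -> MetaGraph:
    """Collapse or expand a metanode (flat view reflects the change)."""
    if state not in ("expanded", "collapsed"):
        raise MetaGraphError(f"unknown state {state!r}")
    g._require_metanode(metanode_id).state = state
    return g


def select_same_properties(
    g: MetaGraph, seed: str, on: str = "data_kind"
) -> set[str]:
    """Nodes sharing the seed's data kind and/or visual customization.

    ``on="data_kind"`` matches the node kind; ``"visual"`` matches the
    shape/color/size properties; ``"both"`` requires kind and visuals.
    """
    if on not in ("data_kind", "visual", "both"):
        raise MetaGraphError(f"unknown selection axis {on!r}")
    if seed not in g.nodes:
        raise MetaGraphError(f"unknown node {seed!r}")
    seed_node = g.nodes[seed]
    seed_visual = tuple(seed_node.properties.get(k) for k in _VISUAL_KEYS)
    out = set()
    for nid, node in g.nodes.items():
        if on in ("data_kind", "both") and node.kind != seed_node.kind:
            continue
        if on in ("visual", "both"):
            if tuple(node.properties.get(k) for k in _VISUAL_KEYS) != seed_visual:
                continue
        out.add(nid)
    return out
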