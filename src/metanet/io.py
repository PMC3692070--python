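"""Network serialization: tab-separated edge lists and a GML subset.

The GML dialect (via networkx) carries node ``kind``, metanode ``members``/
``state``/``origin_term``, and edge ``edge_kind``/``weight``/``method`` tags,
so metagraphs round-trip losslessly.  The edge-list dialect
(``source<TAB>target<TAB>[method]<TAB>[weight]``) is the interchange lowest
common denominator: it flattens metanode structure (with a warning) and
defaults node kinds to gene, overridable through a sidecar kinds table.
Output ordering is sorted by id, so re-serialization is byte-identical.
"""

from __future__ import annotations

import io as _stdio
import warnings
from typing import Mapping

import networkx as nx

from .metagraph import MetaGraph, MetaNode, Node

__all__ = ["FormatError", "read_network", "write_network", "read_kinds_table"]

FORMATS = ("edge_list", "gml")


class FormatError(ValueError):
    pass


def _as_text(stream) -> str:
    if isinstance(stream, str):
        return stream
    return stream.read()


def read_kinds_table(stream) -> dict[str, str]:
    """Sidecar ``node_id<TAB>kind`` table for edge-list imports."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(_as_text(stream).splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip().casefold() == "node_id":
            continue
        if len(fields) < 2:
            raise FormatError(f"kinds table line {lineno}: expected node_id<TAB>kind")
        out[fields[0].strip()] = fields[1].strip()
    return out


def read_network(
    stream, format: str, kinds: Mapping[str, str] | None = None
) -> MetaGraph:
    """Parse an edge-list or GML document into a :class:`MetaGraph`."""
    if format not in FORMATS:
        raise FormatError(f"unknown format {format!r}")
    text = _as_text(stream)
    if format == "edge_list":
        return _read_edge_list(text, kinds or {})
    return _read_gml(text)


def write_network(g: MetaGraph, format: str) -> str:
    """Serialize deterministically (ids sorted).  Metanode membership is
    emitted in GML only; the edge list flattens it with a warning."""
    if format not in FORMATS:
        raise FormatError(f"unknown format {format!r}")
    if format == "edge_list":
        return _write_edge_list(g)
    return _write_gml(g)


# -- edge list ------------------------------------------------------------


def _read_edge_list(text: str, kinds: Mapping[str, str]) -> MetaGraph:
    g = MetaGraph()

    def ensure(nid: str) -> None:
        if nid not in g.nodes:
            g.add_node(Node(nid, kinds.get(nid, "gene")))

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip().casefold() == "source":
            continue
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise FormatError(
                f"line {lineno}: expected source<TAB>target[<TAB>method][<TAB>weight]"
            )
        src, tgt = fields[0].strip(), fields[1].strip()
        method = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
        weight = None
        if len(fields) > 3 and fields[3].strip():
            try:
                weight = float(fields[3])
            except ValueError:
                raise FormatError(f"line {lineno}: bad weight {fields[3]!r}") from None
        ensure(src)
        ensure(tgt)
        g.add_edge(
            src,
            tgt,
            edge_kind="interaction",
            weight=weight,
            methods={method} if method else set(),
        )
    return g


def _write_edge_list(g: MetaGraph) -> str:
    if g.metanodes():
        warnings.warn(
            "edge-list output flattens metanode structure; use GML to keep it",
            stacklevel=2,
        )
    lines = ["source\ttarget\tmethod\tweight"]
    for key in sorted(g.edges):
        e = g.edges[key]
        weight = "" if e.weight is None else format(e.weight, "g")
        # one line per method tag; the reader merges them back onto one edge
        for method in sorted(e.methods) or [""]:
            lines.append(f"{e.u}\t{e.v}\t{method}\t{weight}")
    return "\n".join(lines) + "\n"


# -- GML ------------------------------------------------------------------


def _listify(value) -> list[str]:
    # GML repeated keys collapse to a scalar when there is only one
    if value is None:
        return []
    if isinstance(value, (list, tuple)):
        return [str(v) for v in value]
    return [str(value)]


def _read_gml(text: str) -> MetaGraph:
    try:
        nxg = nx.parse_gml(_stdio.StringIO(text).read().splitlines())
    except nx.NetworkXError as exc:
        raise FormatError(f"malformed GML: {exc}") from exc
    g = MetaGraph()
    meta_members: dict[str, list[str]] = {}
    for nid, data in nxg.nodes(data=True):
        nid = str(nid)
        kind = data.get("kind", "gene")
        properties = {
            k: str(v)
            for k, v in data.items()
            if k not in ("kind", "members", "state", "origin_term", "is_meta", "label")
        }
        if data.get("is_meta"):
            node = MetaNode(
                nid,
                kind,
                properties,
                set(),
                data.get("state", "expanded"),
                data.get("origin_term") or None,
            )
            meta_members[nid] = _listify(data.get("members"))
        else:
            node = Node(nid, kind, properties)
        g.nodes[nid] = node
    for mid, members in meta_members.items():
        missing = [m for m in members if m not in g.nodes]
        if missing:
            raise FormatError(f"metanode {mid!r} lists unknown members {missing!r}")
        g.set_members(mid, members)
    for u, v, data in nxg.edges(data=True):
        g.add_edge(
            str(u),
            str(v),
            edge_kind=data.get("edge_kind", "interaction"),
            weight=data.get("weight"),
            methods=set(_listify(data.get("method"))),
        )
    return g


def _write_gml(g: MetaGraph) -> str:
    # MultiGraph so two edge kinds between one pair survive the round trip
    nxg = nx.MultiGraph()
    for nid in sorted(g.nodes):
        node = g.nodes[nid]
        data: dict = {"kind": node.kind}
        if isinstance(node, MetaNode):
            data["is_meta"] = 1
            data["state"] = node.state
            if node.origin_term:
                data["origin_term"] = node.origin_term
            if node.members:
                data["members"] = sorted(node.members)
        for k in sorted(node.properties):
            data.setdefault(k, node.properties[k])
        nxg.add_node(nid, **data)
    for key in sorted(g.edges):
        e = g.edges[key]
        data = {"edge_kind": e.edge_kind}
        if e.weight is not None:
            data["weight"] = float(e.weight)
        if e.methods:
            data["method"] = sorted(e.methods)
        nxg.add_edge(e.u, e.v, **data)
    return "\n".join(nx.generate_gml(nxg)) + "\n"
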