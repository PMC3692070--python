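"""Shared fixtures: the hand-written worked-example bundle and random-graph
generators for property tests."""

from __future__ import annotations

import numpy as np
import pytest

import metanet as mn
from metanet.metagraph import MetaGraph, MetaNode, Node

FIX1_DISEASE_TSV = """\
term_id\tparent_id\tname
R\t\tdiseases
D1\tR\tcardiovascular disorders
D2\tR\tneoplasms
D1a\tD1\thypertension
"""

FIX1_DRUG_TARGET_TSV = """\
d1\tg1\tM1
d1\tg2\tM1
d2\tg4\tM2
"""


@pytest.fixture
def bundle() -> mn.Bundle:
    return mn.fix1()


@pytest.fixture
def drug_target_graph(bundle) -> MetaGraph:
    """The FIX1 drug-target network: {g1, g2, g4, d1, d2} plus g5."""
    g = MetaGraph()
    for gene in ("g1", "g2", "g4", "g5"):
        g.add_node(Node(gene, "gene"))
    for drug in ("d1", "d2"):
        g.add_node(Node(drug, "drug"))
    for left, right, method in sorted(bundle.tables["drug_target"].records):
        g.add_edge(left, right, edge_kind="drug_target", methods={method})
    return g


def random_metagraph(rng: np.random.Generator, allow_meta: bool = True) -> MetaGraph:
    """A random metagraph: typed component nodes, optional (possibly nested,
    overlapping) metanodes, typed/weighted/tagged edges."""
    g = MetaGraph()
    kinds = ["gene", "drug", "disease", "therapy"]
    n_nodes = int(rng.integers(4, 15))
    ids = [f"n{i}" for i in range(n_nodes)]
    for nid in ids:
        g.add_node(Node(nid, kinds[int(rng.integers(0, 4))]))
    n_edges = int(rng.integers(0, n_nodes * 2))
    for _ in range(n_edges):
        u, v = rng.choice(ids, size=2, replace=False)
        kind = ("interaction", "drug_target", "shared_component")[int(rng.integers(0, 3))]
        weight = float(np.round(rng.random(), 3)) if rng.random() < 0.5 else None
        methods = {f"M{int(rng.integers(0, 3))}"} if rng.random() < 0.7 else set()
        g.add_edge(str(u), str(v), edge_kind=kind, weight=weight, methods=methods)
    if allow_meta:
        n_meta = int(rng.integers(1, 4))
        pool = list(ids)
        for i in range(n_meta):
            mid = f"m{i}"
            size = int(rng.integers(1, max(2, len(pool) // 2 + 1)))
            members = set(str(x) for x in rng.choice(pool, size=size, replace=False))
            meta = MetaNode(mid, "disease", {}, set(), "expanded", None)
            g.add_node(meta)
            g.set_members(mid, members)
            pool.append(mid)  # later metanodes may nest earlier ones
    return g


def random_plain_graph(rng: np.random.Generator) -> MetaGraph:
    """A graph within the edge-list dialect: untyped interaction edges, at
    most one method tag, no metanodes, no isolated nodes."""
    g = MetaGraph()
    n_nodes = int(rng.integers(2, 12))
    ids = [f"v{i}" for i in range(n_nodes)]
    for nid in ids:
        g.add_node(Node(nid, "gene"))
    for _ in range(int(rng.integers(1, n_nodes * 2))):
        u, v = rng.choice(ids, size=2, replace=False)
        weight = float(np.round(rng.random(), 3)) if rng.random() < 0.5 else None
        methods = {f"M{int(rng.integers(0, 3))}"} if rng.random() < 0.7 else set()
        g.add_edge(str(u), str(v), weight=weight, methods=methods)
    for nid in list(g.nodes):
        if not g.incident_edges(nid):
            g.remove_node(nid)
    return g


def brute_force_paths(parents: dict[str, set[str]], start: str) -> list[list[str]]:
    """Independent exhaustive enumeration of parent-walks to the roots."""
    out: list[list[str]] = []

    def walk(node: str, acc: list[str]) -> None:
        ps = parents.get(node, set())
        if not ps:
            out.append(list(acc))
            return
        for p in sorted(ps):
            walk(p, acc + [p])

    walk(start, [start])
    return sorted(out)
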