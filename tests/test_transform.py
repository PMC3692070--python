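"""Network transformations and the 11-type factory."""

from itertools import combinations

import numpy as np
import pytest

import metanet as mn
from metanet.metagraph import MetaGraph, MetaGraphError, Node
from metanet.transform import TYPE_KINDS


def _edge_set(g: MetaGraph):
    return {(e.u, e.v, e.edge_kind) for e in g.edges.values()}


def _weights(g: MetaGraph):
    return {(e.u, e.v, e.edge_kind): e.weight for e in g.edges.values()}


def _disease_meta(bundle, terms=("D1", "D2"), mode="all_components"):
    g = MetaGraph()
    for t in terms:
        mn.add_metanode(g, bundle.disease_hierarchy, bundle.disease_annotations, t, mode)
    return g


class TestBipartite:
    def test_flat_metanode(self, bundle):
        g = _disease_meta(bundle, terms=("D1",))
        out = mn.bipartite_transform(g, ["D1"])
        assert not out.metanodes()
        assert _edge_set(out) == {
            ("D1", "g1", "disease_gene"),
            ("D1", "g2", "disease_gene"),
            ("D1", "g3", "disease_gene"),
        }

    def test_nested_metanode_links_innermost_term_only(self, bundle):
        g = _disease_meta(bundle, terms=("D1",), mode="all_with_subterms")
        out = mn.bipartite_transform(g, ["D1"])
        assert _edge_set(out) == {
            ("D1", "g3", "disease_gene"),
            ("D1a", "g1", "disease_gene"),
            ("D1a", "g2", "disease_gene"),
        }

    def test_empty_metanode_becomes_isolated_node(self, bundle):
        g = MetaGraph()
        with pytest.warns(UserWarning):
            mn.add_metanode(g, bundle.disease_hierarchy, bundle.disease_annotations,
                            "D1", "existing_components_only")
        out = mn.bipartite_transform(g, ["D1"])
        assert out.nodes["D1"].kind == "disease"
        assert not out.edges

    def test_non_metanode_rejected(self, bundle):
        g = _disease_meta(bundle, terms=("D1",))
        with pytest.raises(MetaGraphError):
            mn.bipartite_transform(g, ["g1"])

    def test_term_degree_equals_flattened_member_count(self):
        rng = np.random.default_rng(31)
        for seed in range(10):
            b = mn.generate_fixture(mn.FixtureSpec(seed=seed, n_terms=13, n_genes=40))
            g = MetaGraph()
            terms = sorted(b.disease_hierarchy.children(next(iter(b.disease_hierarchy.roots))))
            for t in terms:
                mn.add_metanode(g, b.disease_hierarchy, b.disease_annotations, t)
            flattened = {t: g.flattened_members(t) for t in terms}
            out = mn.bipartite_transform(g, terms)
            for t in terms:
                deg = sum(1 for e in out.edges.values()
                          if t in (e.u, e.v) and e.edge_kind == "disease_gene")
                assert deg == len(flattened[t])


class TestCoMetanode:
    def test_fix1_pairs(self, bundle):
        g = _disease_meta(bundle)
        out = mn.co_metanode_transform(g, ["D1", "D2"])
        assert _weights(out) == {
            ("g1", "g2", "co_membership"): 1.0,
            ("g1", "g3", "co_membership"): 1.0,
            ("g2", "g3", "co_membership"): 1.0,
            ("g2", "g4", "co_membership"): 1.0,
        }

    def test_shared_pair_weight_two(self):
        g = MetaGraph()
        for nid in ("x", "y"):
            g.add_node(Node(nid, "gene"))
        from metanet.metagraph import MetaNode
        for mid in ("mA", "mB"):
            g.add_node(MetaNode(mid, "disease"))
            g.set_members(mid, {"x", "y"})
        out = mn.co_metanode_transform(g, ["mA", "mB"])
        assert _weights(out) == {("x", "y", "co_membership"): 2.0}

    def test_singleton_metanode_adds_no_edges(self, bundle):
        g = _disease_meta(bundle, terms=("D1a",))
        g.metanodes()["D1a"].members = {"g1"}
        out = mn.co_metanode_transform(g, ["D1a"])
        assert not out.edges


class TestSharedComponents:
    def test_fix1_overlap(self, bundle):
        g = _disease_meta(bundle)
        (edge,) = mn.shared_component_edges(g, ["D1", "D2"])
        assert {edge.u, edge.v} == {"D1", "D2"}
        assert edge.weight == 1.0  # intersection {g2}

    def test_disjoint_metanodes_no_edge(self, bundle):
        g = _disease_meta(bundle, terms=("D1a",))
        mn.add_metanode(g, bundle.therapy_hierarchy, bundle.therapy_annotations, "T1")
        assert mn.shared_component_edges(g, ["D1a", "T1"]) == []

    def test_three_metanode_intersections(self):
        from metanet.metagraph import MetaNode
        g = MetaGraph()
        for nid in "abc":
            g.add_node(Node(nid, "gene"))
        for mid, members in (("m1", {"a", "b"}), ("m2", {"b", "c"}), ("m3", {"a", "b", "c"})):
            g.add_node(MetaNode(mid, "disease"))
            g.set_members(mid, members)
        edges = mn.shared_component_edges(g, ["m1", "m2", "m3"])
        got = {(e.u, e.v): e.weight for e in edges}
        assert got == {("m1", "m2"): 1.0, ("m1", "m3"): 2.0, ("m2", "m3"): 2.0}

    def test_jaccard_mode(self, bundle):
        g = _disease_meta(bundle)
        (edge,) = mn.shared_component_edges(g, ["D1", "D2"], weight_mode="jaccard")
        assert edge.weight == pytest.approx(1 / 4)  # |{g2}| / |{g1,g2,g3,g4}|


class TestInteractionBased:
    def test_gene_gene_link(self, bundle):
        g = _disease_meta(bundle, terms=("D1a",))
        g.metanodes()["D1a"].members = {"g1"}
        from metanet.metagraph import MetaNode
        g.add_node(Node("g2", "gene"))
        g.add_node(MetaNode("X", "disease"))
        g.set_members("X", {"g2"})
        (edge,) = mn.interaction_based_edges(g, ["D1a", "X"], bundle.tables["gene_gene"])
        assert edge.weight == 1.0

    def test_therapy_disease_drug_target_record(self, bundle):
        g = MetaGraph()
        mn.add_metanode(g, bundle.therapy_hierarchy, bundle.therapy_annotations, "T1")
        mn.add_metanode(g, bundle.disease_hierarchy, bundle.disease_annotations, "D2")
        edges = mn.interaction_based_edges(g, ["T1", "D2"], bundle.tables["drug_target"])
        (edge,) = edges
        # d2 (in T1) targets g4 (in D2); d1 targets g2 which is also in D2
        assert {edge.u, edge.v} == {"D2", "T1"}
        assert edge.weight == 2.0
        assert edge.methods == {"drug_target"}

    def test_no_cross_records_no_edges(self, bundle):
        g = _disease_meta(bundle, terms=("D1a", "D2"))
        empty = mn.AssociationTable("gene_gene")
        assert mn.interaction_based_edges(g, ["D1a", "D2"], empty) == []


class TestDeriveNetwork:
    def _derive(self, bundle, network_type, d_terms=("D1", "D2"), t_terms=("T1", "T2")):
        return mn.derive_network(
            bundle.disease_hierarchy, bundle.therapy_hierarchy,
            bundle.disease_annotations, bundle.therapy_annotations,
            bundle.tables, list(d_terms), list(t_terms), network_type,
        )

    def test_disease_gene_fix1(self, bundle):
        net = self._derive(bundle, "disease_gene", d_terms=("D1",), t_terms=())
        assert set(net.nodes) == {"D1", "g1", "g2", "g3"}
        assert len(net.edges) == 3

    def test_disease_gene_drug_fix1(self, bundle):
        net = self._derive(bundle, "disease_gene_drug", d_terms=("D1",), t_terms=())
        assert set(net.nodes) == {"D1", "g1", "g2", "g3", "d1"}  # g3 untargeted
        assert _edge_set(net) >= {("d1", "g1", "drug_target"), ("d1", "g2", "drug_target")}

    def test_therapy_drug_gene_fix1(self, bundle):
        net = self._derive(bundle, "therapy_drug_gene", d_terms=(), t_terms=("T2",))
        assert set(net.nodes) == {"T2", "d2", "g4"}
        assert _edge_set(net) == {("T2", "d2", "therapy_drug"), ("d2", "g4", "drug_target")}

    @pytest.mark.parametrize("network_type", list(mn.NetworkType))
    def test_all_types_derive_with_declared_kinds(self, bundle, network_type):
        net = self._derive(bundle, network_type)
        assert net.node_kinds() <= TYPE_KINDS[network_type]
        assert net.nodes  # FIX1 populates every type

    def test_missing_table_is_named(self, bundle):
        with pytest.raises(MetaGraphError, match="drug_target"):
            mn.derive_network(
                bundle.disease_hierarchy, bundle.therapy_hierarchy,
                bundle.disease_annotations, bundle.therapy_annotations,
                {}, ["D1"], ["T1"], "disease_therapy",
            )

    def test_co_disease_gene_matches_manual_chain(self, bundle):
        derived = self._derive(bundle, "co_disease_gene")
        manual = mn.co_metanode_transform(_disease_meta(bundle), ["D1", "D2"])
        assert _weights(derived) == _weights(manual)
        assert set(derived.nodes) == set(manual.nodes)

    def test_disease_gene_matches_manual_chain(self, bundle):
        derived = self._derive(bundle, "disease_gene")
        manual = mn.bipartite_transform(_disease_meta(bundle), ["D1", "D2"])
        assert _edge_set(derived) == _edge_set(manual)
        assert set(derived.nodes) == set(manual.nodes)


class TestProjectionOracles:
    """Brute-force pair/intersection enumeration on random bundles."""

    def test_co_membership_and_shared_components_match_brute_force(self):
        for seed in range(20):
            b = mn.generate_fixture(
                mn.FixtureSpec(seed=seed, n_terms=13, n_genes=40, annotation_density=0.15)
            )
            g = MetaGraph()
            root = next(iter(b.disease_hierarchy.roots))
            terms = sorted(b.disease_hierarchy.children(root))
            for t in terms:
                mn.add_metanode(g, b.disease_hierarchy, b.disease_annotations, t)
            members = {t: set(g.flattened_members(t)) for t in terms}

            out = mn.co_metanode_transform(g, terms)
            expected: dict[tuple[str, str], float] = {}
            for t in terms:
                for u, v in combinations(sorted(members[t]), 2):
                    expected[(u, v)] = expected.get((u, v), 0.0) + 1.0
            assert {(e.u, e.v): e.weight for e in out.edges.values()} == expected

            shared = mn.shared_component_edges(g, terms)
            got = {(e.u, e.v): e.weight for e in shared}
            want = {
                tuple(sorted((t1, t2))): float(len(members[t1] & members[t2]))
                for t1, t2 in combinations(terms, 2)
                if members[t1] & members[t2]
            }
            assert got == want
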