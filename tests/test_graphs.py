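"""Graph container, I/O round-trips, permutation invariants and generators."""

import logging
import math

import numpy as np
import pytest

from solspace import (
    Graph,
    RingOfCliquesSpec,
    erdos_renyi,
    permute,
    read_edgelist,
    read_graphml,
    ring_of_cliques,
    write_edgelist,
    write_graphml,
)
from solspace.graphs import GraphParseError, GraphValidationError


class TestGraphInvariants:
    def test_rejects_self_loop_duplicate_and_unknown_endpoint(self):
        with pytest.raises(GraphValidationError):
            Graph(["a", "b"], [("a", "a")])
        with pytest.raises(GraphValidationError):
            Graph(["a", "b"], [("a", "b"), ("b", "a")])
        with pytest.raises(GraphValidationError):
            Graph(["a", "b"], [("a", "c")])
        with pytest.raises(GraphValidationError):
            Graph(["a", "a"], [])
        with pytest.raises(GraphValidationError):
            Graph([], [])

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(GraphValidationError):
            Graph(["a", "b"], [("a", "b", 0.0)])
        with pytest.raises(GraphValidationError):
            Graph(["a", "b"], [("a", "b", -1.0)])

    def test_default_weight_and_counts(self, triangle):
        assert triangle.n_v == 3 and triangle.n_e == 3
        assert not triangle.is_weighted
        assert all(w == 1.0 for _, _, w in triangle.edges)


class TestEdgelistIO:
    def test_triangle_roundtrip(self, tmp_path, triangle):
        path = tmp_path / "tri.csv"
        write_edgelist(triangle, path)
        g = read_edgelist(path)
        assert g.n_v == 3 and g.n_e == 3
        assert g.same_abstract_graph(triangle)
        assert g.nodes == triangle.nodes  # first-appearance order preserved

    def test_duplicate_edges_collapse_with_warning(self, tmp_path, caplog):
        path = tmp_path / "dup.csv"
        path.write_text("a,b\nb,a\nb,c\n")
        with caplog.at_level(logging.WARNING):
            g = read_edgelist(path)
        assert g.n_e == 2
        weights = {frozenset((u, v)): w for u, v, w in g.edges}
        assert weights[frozenset(("a", "b"))] == 2.0
        assert any("collapsed" in rec.message for rec in caplog.records)

    def test_rcc_write_read_isomorphic(self, tmp_path, rcc_graph):
        path = tmp_path / "rcc.csv"
        write_edgelist(rcc_graph, path)
        g = read_edgelist(path)
        assert (g.n_v, g.n_e) == (21, 48)
        assert g.same_abstract_graph(rcc_graph)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("source,target,weight\na,b,1.0\nc\n")
        with pytest.raises(GraphParseError, match="line 3"):
            read_edgelist(path)

    def test_nonpositive_weight_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,-2\n")
        with pytest.raises(GraphValidationError, match="line 1"):
            read_edgelist(path)

    def test_header_detected_by_names_without_weight_column(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("source,target\na,b\n")
        g = read_edgelist(path)
        assert g.nodes == ["a", "b"] and g.n_e == 1

    def test_tsv_delimiter(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("a\tb\t2.5\nb\tc\t1\n")
        g = read_edgelist(path, delimiter="\t")
        assert g.n_e == 2 and g.is_weighted

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(GraphParseError):
            read_edgelist(path)


class TestGraphML:
    def test_roundtrip_preserves_everything(self, tmp_path, rcc_graph):
        path = tmp_path / "g.graphml"
        write_graphml(rcc_graph, path)
        g = read_graphml(path)
        assert g.nodes == rcc_graph.nodes
        assert g.edge_multiset() == rcc_graph.edge_multiset()

    def test_weighted_roundtrip(self, tmp_path):
        g0 = Graph(["x", "y", "z"], [("x", "y", 2.5), ("y", "z", 0.5)])
        path = tmp_path / "w.graphml"
        write_graphml(g0, path)
        g = read_graphml(path)
        assert g.edge_multiset() == g0.edge_multiset()

    def test_directed_rejected(self, tmp_path):
        import networkx as nx

        path = tmp_path / "d.graphml"
        nx.write_graphml(nx.DiGraph([("a", "b")]), path)
        with pytest.raises(GraphValidationError, match="directed"):
            read_graphml(path)

    def test_nodeless_rejected(self, tmp_path):
        import networkx as nx

        path = tmp_path / "e.graphml"
        nx.write_graphml(nx.Graph(), path)
        with pytest.raises(GraphParseError):
            read_graphml(path)


class TestPermute:
    def test_information_preserving(self, rcc_graph):
        for seed in range(5):
            gp = permute(rcc_graph, seed)
            assert gp.same_abstract_graph(rcc_graph)
            assert gp.degree_sequence() == rcc_graph.degree_sequence()

    def test_order_changes_across_seeds(self, rcc_graph):
        orders = {tuple(permute(rcc_graph, s).nodes) for s in range(10)}
        assert len(orders) > 1

    def test_weighted_graph_weights_untouched(self):
        g = Graph(["a", "b", "c"], [("a", "b", 3.0), ("b", "c", 0.5)])
        gp = permute(g, 7)
        assert gp.edge_multiset() == g.edge_multiset()


class TestGenerators:
    @pytest.mark.parametrize(
        "nc,cs,central,n_v,n_e",
        [
            (4, 5, True, 21, 48),  # 4*C(5,2) + 4 ring + 4 centre
            (4, 5, False, 20, 44),
            (2, 3, False, 6, 7),  # two cliques joined by a single bridge edge
            (3, 3, True, 10, 15),  # 9 intra + 3 ring + 3 centre
        ],
    )
    def test_ring_of_cliques_counts(self, nc, cs, central, n_v, n_e):
        g = ring_of_cliques(RingOfCliquesSpec(nc, cs, central_node=central))
        assert (g.n_v, g.n_e) == (n_v, n_e)

    def test_cliques_are_complete(self):
        spec = RingOfCliquesSpec(3, 4, central_node=True)
        g = ring_of_cliques(spec)
        adj = g.adjacency()
        for i in range(3):
            members = spec.clique_members(i)
            for a in members:
                for b in members:
                    if a != b:
                        assert b in adj[a]

    def test_central_node_one_edge_per_clique(self, rcc_graph):
        adj = rcc_graph.adjacency()
        assert adj["centre"] == {f"c{i}_n0" for i in range(4)}

    def test_deterministic(self, rcc_spec):
        g1, g2 = ring_of_cliques(rcc_spec), ring_of_cliques(rcc_spec)
        assert g1.nodes == g2.nodes and g1.edges == g2.edges

    def test_spec_validation(self):
        with pytest.raises(GraphValidationError):
            RingOfCliquesSpec(1, 5)
        with pytest.raises(GraphValidationError):
            RingOfCliquesSpec(4, 2)

    def test_erdos_renyi_extremes(self):
        assert erdos_renyi(10, 0.0, 0).n_e == 0
        assert erdos_renyi(10, 1.0, 0).n_e == math.comb(10, 2)

    def test_erdos_renyi_edge_count_within_4_sigma(self):
        g = erdos_renyi(100, 0.05, seed=3)
        mean = math.comb(100, 2) * 0.05
        sigma = math.sqrt(math.comb(100, 2) * 0.05 * 0.95)
        assert abs(g.n_e - mean) < 4 * sigma

    def test_erdos_renyi_validation(self):
        with pytest.raises(GraphValidationError):
            erdos_renyi(10, 1.5, 0)
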