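"""Partition similarity, exact matching, validity and degeneracy checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solspace import (
    Graph,
    Partition,
    nmi,
    read_edgelist,
    same_partition,
    validate,
)
from solspace.partitions import (
    ALL_ONE_COMMUNITY,
    ALL_SINGLETONS,
    DISCONNECTED_COMMUNITY,
    INTER_GT_INTRA,
    read_partition_csv,
    read_partition_json,
    write_partition_csv,
    write_partition_json,
)


def _relabel(p: Partition, offset=100) -> Partition:
    return Partition({n: f"x{hash(l) % 7}_{l}" for n, l in p.assignment.items()})


class TestNMI:
    def test_identity_and_label_invariance(self, rcc_refs):
        p = rcc_refs["P1"]
        assert nmi(p, p) == pytest.approx(1.0)
        assert nmi(p, _relabel(p)) == pytest.approx(1.0)

    def test_orthogonal_four_nodes(self):
        p1 = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        p2 = Partition({"a": 0, "b": 1, "c": 0, "d": 1})
        assert nmi(p1, p2) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, rcc_refs):
        p1, p2 = rcc_refs["P1"], rcc_refs["P_singleton"]
        assert nmi(p1, p2) == pytest.approx(nmi(p2, p1))

    def test_node_set_mismatch_errors(self):
        with pytest.raises(ValueError):
            nmi(Partition({"a": 0}), Partition({"b": 0}))

    def test_unknown_normalization(self, rcc_refs):
        with pytest.raises(ValueError):
            nmi(rcc_refs["P1"], rcc_refs["P2"], normalization="harmonic")

    @pytest.mark.parametrize("norm", ["arithmetic", "min", "max", "sqrt"])
    def test_all_normalizations_agree_at_one(self, rcc_refs, norm):
        p = rcc_refs["P3"]
        assert nmi(p, _relabel(p), normalization=norm) == pytest.approx(1.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        l1=st.lists(st.integers(0, 5), min_size=2, max_size=6),
        l2=st.lists(st.integers(0, 5), min_size=2, max_size=6),
    )
    def test_same_partition_iff_nmi_one(self, l1, l2):
        """same_partition agrees with the NMI = 1 rule and with a brute-force
        set-of-frozensets comparison, on random small partitions."""
        n = min(len(l1), len(l2))
        nodes = [f"n{i}" for i in range(n)]
        p1 = Partition(dict(zip(nodes, l1)))
        p2 = Partition(dict(zip(nodes, l2)))
        brute = frozenset(p1.communities()) == frozenset(p2.communities())
        assert same_partition(p1, p2) == brute
        v = nmi(p1, p2)
        assert 0.0 - 1e-12 <= v <= 1.0 + 1e-12
        if brute:
            assert v >= 1.0 - 1e-12
        else:
            assert v < 1.0 - 1e-12


class TestCanonicalForm:
    def test_relabel_invariant(self, rcc_refs):
        p = rcc_refs["P2"]
        assert p.canonical_form() == _relabel(p).canonical_form()

    def test_distinct_partitions_differ(self, rcc_refs):
        forms = {p.canonical_form() for p in rcc_refs.values()}
        assert len(forms) == len(rcc_refs)

    def test_single_node(self):
        assert Partition({"a": "z"}).canonical_form() == ((("a",),))

    def test_centre_placement_distinguishes_references(self, rcc_refs):
        assert not same_partition(rcc_refs["P5" if "P5" in rcc_refs else "P_singleton"], rcc_refs["P1"])

    def test_one_node_moved_differs(self, rcc_refs):
        p = rcc_refs["P1"]
        a = dict(p.assignment)
        a["c1_n1"] = a["c0_n0"]
        assert not same_partition(p, Partition(a))


class TestValidate:
    def test_singleton_centre_partition_valid(self, rcc_graph, rcc_refs):
        rep = validate(rcc_graph, rcc_refs["P_singleton"])
        assert rep.is_valid and not rep.is_degenerate
        # 40 clique-internal edges are intra; 4 ring + 4 centre edges cross
        assert (rep.intra_edges, rep.inter_edges) == (40, 8)

    def test_centre_in_clique_partition_valid(self, rcc_graph, rcc_refs):
        rep = validate(rcc_graph, rcc_refs["P1"])
        assert rep.is_valid and not rep.is_degenerate
        assert rep.intra_edges + rep.inter_edges == rcc_graph.n_e

    def test_all_one_community(self, rcc_graph):
        p = Partition({n: 0 for n in rcc_graph.nodes})
        rep = validate(rcc_graph, p)
        assert not rep.is_valid and ALL_ONE_COMMUNITY in rep.reasons

    def test_all_singletons(self, triangle):
        rep = validate(triangle, Partition({"a": 0, "b": 1, "c": 2}))
        assert not rep.is_valid and ALL_SINGLETONS in rep.reasons
        # all singletons also have zero intra edges -> degenerate
        assert rep.is_degenerate and INTER_GT_INTRA in rep.reasons

    def test_disconnected_community_detected(self, rcc_graph, rcc_refs):
        # strand two non-adjacent members of clique 0 with the community of clique 2
        a = dict(rcc_refs["P1"].assignment)
        a["c0_n1"] = a["c2_n0"]
        a["c0_n2"] = a["c2_n0"]
        rep = validate(rcc_graph, Partition(a))
        assert not rep.is_valid and DISCONNECTED_COMMUNITY in rep.reasons

    def test_connected_components_partition_never_disconnected(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            nodes = [f"v{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.25
            ]
            g = Graph(nodes, edges)
            # label nodes by connected component
            adj = g.adjacency()
            label, comp = {}, 0
            for start in nodes:
                if start in label:
                    continue
                stack = [start]
                while stack:
                    u = stack.pop()
                    if u in label:
                        continue
                    label[u] = comp
                    stack.extend(adj[u])
                comp += 1
            rep = validate(g, Partition(label))
            assert DISCONNECTED_COMMUNITY not in rep.reasons

    def test_weighted_degeneracy_switch(self):
        g = Graph(["a", "b", "c", "d"], [("a", "b", 1.0), ("c", "d", 1.0), ("b", "c", 10.0)])
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        assert not validate(g, p, weighted=False).is_degenerate  # 2 intra vs 1 inter
        assert validate(g, p, weighted=True).is_degenerate  # 2.0 intra vs 10.0 inter

    def test_node_mismatch_errors(self, rcc_graph):
        with pytest.raises(ValueError):
            validate(rcc_graph, Partition({"a": 0}))


class TestPartitionIO:
    def test_csv_roundtrip_canonical_labels(self, tmp_path, rcc_refs):
        p = rcc_refs["P3"]
        path = tmp_path / "p.csv"
        write_partition_csv(p, path)
        q = read_partition_csv(path)
        assert same_partition(p, q)
        labels = list(q.canonical_labels().values())
        assert set(labels) == set(range(p.k))

    def test_json_roundtrip(self, tmp_path, rcc_refs):
        p = rcc_refs["P_singleton"]
        path = tmp_path / "p.json"
        write_partition_json(p, path)
        assert same_partition(p, read_partition_json(path))
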