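"""Centrality computation, H-B classification, quarters and consensus."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_graph
from oracles import brute_betweenness

from cpnet import centrality as ct
from cpnet.errors import CpnetWarning, InputError


def records_of(graph):
    for n in graph.nodes:
        graph.nodes[n].setdefault("kind", "protein")
    return ct.compute_centralities(graph)


class TestComputeCentralities:
    def test_path_graph(self):
        rec = records_of(nx.path_graph(["a", "b", "c"])).set_index("node")
        assert rec.loc["b", "betweenness"] == 1.0
        assert rec.loc["a", "betweenness"] == 0.0
        assert rec.loc["c", "betweenness"] == 0.0

    def test_star_graph(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        rec = records_of(g).set_index("node")
        assert rec.loc[0, "betweenness"] == 6.0  # C(4,2)
        assert rec.loc[0, "degree"] == 4
        assert (rec.loc[1:, "betweenness"] == 0.0).all()

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            g = random_graph(rng, 30, 0.15)
            rec = records_of(g).set_index("node")
            oracle = brute_betweenness(g)
            for node, expected in oracle.items():
                assert rec.loc[node, "betweenness"] == pytest.approx(expected, abs=1e-9)
                assert rec.loc[node, "degree"] == g.degree[node]

    def test_tree_closed_form(self):
        # in a tree the unique s-t path crosses v iff s and t lie in
        # different components of T - v; count those pairs directly
        rng = np.random.default_rng(5)
        for seed in range(5):
            t = nx.random_labeled_tree(12, seed=int(rng.integers(2**31)))
            rec = records_of(t).set_index("node")
            for v in t.nodes:
                rest = t.subgraph(set(t.nodes) - {v})
                sizes = [len(c) for c in nx.connected_components(rest)]
                crossing = (sum(sizes) ** 2 - sum(s * s for s in sizes)) / 2
                assert rec.loc[v, "betweenness"] == pytest.approx(crossing)

    def test_betweenness_sum_equals_oracle_total(self):
        rng = np.random.default_rng(3)
        g = random_graph(rng, 20, 0.2)
        rec = records_of(g)
        assert rec["betweenness"].sum() == pytest.approx(
            sum(brute_betweenness(g).values())
        )

    def test_exclude_chemicals(self):
        g = nx.path_graph(["a", "chem", "b"])
        for n in g.nodes:
            g.nodes[n]["kind"] = "chemical" if n == "chem" else "protein"
        rec = ct.compute_centralities(g, include_chemicals=False)
        assert set(rec["node"]) == {"a", "b"}

    def test_too_small_raises(self):
        with pytest.raises(InputError):
            records_of(nx.empty_graph(1))


class TestClassifyHb:
    def test_cycle_has_no_hubs_or_bottlenecks(self):
        rec, th = ct.classify_hb(records_of(nx.cycle_graph(6)))
        assert (rec["hb_class"] == ct.NH_NB).all()

    def test_star_center_is_hb(self):
        rec, th = ct.classify_hb(records_of(nx.star_graph(4)))
        by = rec.set_index("node")["hb_class"]
        assert by[0] == ct.HB
        assert (by.drop(0) == ct.NH_NB).all()

    def test_hand_worked_graph(self):
        # two hubs b, f joined by a bridge; leaves hang off each hub
        g = nx.Graph(
            [("a", "b"), ("c", "b"), ("d", "b"), ("b", "f"),
             ("f", "g"), ("f", "h"), ("f", "i"), ("x", "a")]
        )
        rec, th = ct.classify_hb(records_of(g))
        by = rec.set_index("node")
        # degrees: b=4, f=4, a=2, others 1 -> mean = 16/9
        assert th.degree_mean == pytest.approx(16 / 9)
        assert by.loc["b", "hb_class"] == ct.HB
        assert by.loc["f", "hb_class"] == ct.HB
        # a: degree 2 > mean, betweenness(a)=7 (x to everything) > mean
        assert by.loc["a", "hb_class"] == ct.HB
        assert by.loc["x", "hb_class"] == ct.NH_NB

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            g = random_graph(rng, 25, 0.15)
            rec, _ = ct.classify_hb(records_of(g))
            assert rec["hb_class"].isin([ct.HB, ct.H_NB, ct.NH_B, ct.NH_NB]).all()
            assert len(rec) == g.number_of_nodes()


class TestHbSubnetwork:
    def test_star_subnetwork_is_isolated_center(self):
        g = nx.star_graph(4)
        rec, _ = ct.classify_hb(records_of(g))
        sub = ct.hb_subnetwork(g, rec)
        assert set(sub.nodes) == {0}
        assert sub.number_of_edges() == 0

    def test_induced_subgraph_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            g = random_graph(rng, 25, 0.2)
            rec, _ = ct.classify_hb(records_of(g))
            hb = ct.hb_nodes(rec)
            if not hb:
                continue
            sub = ct.hb_subnetwork(g, rec)
            assert set(sub.nodes) == hb
            for u in hb:
                for v in hb:
                    assert sub.has_edge(u, v) == g.has_edge(u, v)

    def test_no_hb_warns(self):
        g = nx.cycle_graph(5)
        rec, _ = ct.classify_hb(records_of(g))
        with pytest.warns(CpnetWarning):
            sub = ct.hb_subnetwork(g, rec)
        assert sub.number_of_nodes() == 0


class TestQuarters:
    def frame(self, rows):
        df = pd.DataFrame(rows, columns=["node", "degree", "betweenness", "hb_class"])
        df["kind"] = "protein"
        return df

    def test_two_node_split(self):
        rec = self.frame([("a", 1, 1.0, ct.HB), ("b", 3, 3.0, ct.HB)])
        out, dmed, bmed = ct.assign_quarters(rec)
        by = out.set_index("node")["quarter"]
        assert (dmed, bmed) == (2.0, 2.0)
        assert by["b"] == "Q4"
        assert by["a"] == "Q1"

    def test_identical_hb_nodes_have_empty_q4(self):
        rec = self.frame([("a", 2, 2.0, ct.HB), ("b", 2, 2.0, ct.HB)])
        out, *_ = ct.assign_quarters(rec)
        assert (out["quarter"] == "Q1").all()

    def test_hand_computed_fixture(self):
        rows = [(f"n{i}", d, b, ct.HB) for i, (d, b) in enumerate(
            [(1, 9.0), (2, 8.0), (3, 7.0), (4, 6.0), (5, 5.0), (6, 4.0),
             (7, 3.0), (8, 2.0)]
        )] + [(f"m{i}", 1, 0.0, ct.NH_NB) for i in range(4)]
        out, dmed, bmed = ct.assign_quarters(self.frame(rows))
        assert (dmed, bmed) == (4.5, 5.5)  # medians over H-B only
        by = out.set_index("node")["quarter"]
        assert by["n0"] == "Q2" and by["n7"] == "Q3"
        assert by["n4"] == "Q3"  # degree 5 > 4.5, betweenness 5 < 5.5
        assert by["n3"] == "Q2"  # degree 4 < 4.5, betweenness 6 > 5.5
        assert (out.loc[out["hb_class"] != ct.HB, "quarter"] == "none").all()

    def test_needs_hb_nodes(self):
        with pytest.raises(InputError):
            ct.assign_quarters(self.frame([("a", 1, 1.0, ct.NH_NB)]))


class TestConsensus:
    def test_identical_sets(self):
        consensus, venn = ct.consensus_hb([{"a", "b"}, {"a", "b"}, {"a", "b"}])
        assert consensus == {"a", "b"}
        assert venn["a"] == (True, True, True)

    def test_disjoint_sets_empty(self):
        consensus, _ = ct.consensus_hb([{"a"}, {"b"}])
        assert consensus == set()

    def test_three_way_example(self):
        consensus, venn = ct.consensus_hb([{"A", "B", "C"}, {"B", "C", "D"}, {"C", "B"}])
        assert consensus == {"B", "C"}
        assert venn["D"] == (False, True, False)

    def test_degree_monotone_under_edge_addition(self):
        rng = np.random.default_rng(33)
        g = random_graph(rng, 15, 0.2)
        rec_before = records_of(g).set_index("node")["degree"]
        non_edges = list(nx.non_edges(g))
        if non_edges:
            u, v = non_edges[0]
            g.add_edge(u, v)
            rec_after = records_of(g).set_index("node")["degree"]
            assert (rec_after >= rec_before).all()
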