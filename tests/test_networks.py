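"""Term networks, Signal-Net construction, centralities and core-gene ranking."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rvmnet import (
    DEGeneList, InteractionEdgeList, SignalNetwork,
    betweenness, build_signal_net, build_term_network,
    clustering_coefficient, degrees, rank_core_genes,
)
from rvmnet.errors import InvalidInputError
from _oracles import betweenness_enumeration, random_directed_graphs


def _net(edge_pairs, styles=None, undirected=False) -> SignalNetwork:
    g = nx.DiGraph()
    for u, v in edge_pairs:
        g.add_edge(u, v, relations={"a"})
        if undirected:
            g.add_edge(v, u, relations={"a"})
    styles = styles or {v: "up" for v in g.nodes}
    return SignalNetwork(graph=g, styles=styles)


def _de_list(genes_up, genes_down=()):
    rows = [{"gene_id": g, "direction": "up", "p": 0.01, "fold_change": 2.0, "t_rvm": 2.0}
            for g in genes_up]
    rows += [{"gene_id": g, "direction": "down", "p": 0.01, "fold_change": 0.5, "t_rvm": -2.0}
             for g in genes_down]
    return DEGeneList(selected=pd.DataFrame(rows, columns=["gene_id", "direction", "p",
                                                           "fold_change", "t_rvm"]), alpha=0.05)


class TestTermNetwork:
    @staticmethod
    def _records(sig_up, sig_down, extra=()):
        rows = []
        for t in sig_up:
            rows.append({"term_id": t, "direction_class": "up", "significant": True})
        for t in sig_down:
            rows.append({"term_id": t, "direction_class": "down", "significant": True})
        for t in extra:
            rows.append({"term_id": t, "direction_class": "up", "significant": False})
        return pd.DataFrame(rows)

    def test_no_significant_terms(self):
        tg = build_term_network(self._records([], [], extra=["T1"]), [("T1", "T1")])
        assert tg.graph.number_of_nodes() == 0

    def test_both_class(self):
        tg = build_term_network(self._records(["T1"], ["T1", "T2"]), [])
        assert tg.node_class("T1") == "both"
        assert tg.node_class("T2") == "down"

    def test_path_relations_restricted_to_nodes(self):
        recs = self._records(["T1", "T2", "T3", "T4", "T5"], [])
        tg = build_term_network(recs, [("T1", "T2"), ("T2", "T3")])
        assert tg.graph.number_of_nodes() == 5
        assert tg.graph.number_of_edges() == 2

    def test_unknown_term_relation_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            tg = build_term_network(self._records(["T1"], []), [("T1", "TX")])
        assert "unknown term" in caplog.text
        assert tg.graph.number_of_edges() == 0


class TestBuildSignalNet:
    def test_empty_de_list(self, caplog):
        edges = InteractionEdgeList(edges=[("A", "B", "a", True)])
        with caplog.at_level("WARNING"):
            net = build_signal_net(edges, _de_list([]))
        assert net.n == 0

    def test_induced_subgraph(self):
        edges = InteractionEdgeList(edges=[
            ("A", "B", "a", True), ("B", "C", "inh", True), ("C", "D", "a", True),
        ])
        net = build_signal_net(edges, _de_list(["A", "B", "C"]))
        assert set(net.graph.nodes) == {"A", "B", "C"}
        assert set(net.graph.edges) == {("A", "B"), ("B", "C")}

    def test_undirected_edge_symmetric(self):
        edges = InteractionEdgeList(edges=[("A", "B", "b", False)])
        net = build_signal_net(edges, _de_list(["A"], ["B"]))
        assert net.graph.has_edge("A", "B") and net.graph.has_edge("B", "A")

    def test_styles_follow_de_direction(self):
        edges = InteractionEdgeList(edges=[("A", "B", "a", True)])
        net = build_signal_net(edges, _de_list(["A"], ["B"]))
        assert net.styles == {"A": "up", "B": "down"}

    def test_edge_list_validation(self):
        with pytest.raises(InvalidInputError):
            InteractionEdgeList(edges=[("A", "A", "a", True)])
        with pytest.raises(InvalidInputError):
            InteractionEdgeList(edges=[("A", "B", "zz", True)])

    def test_duplicate_triples_dropped(self):
        e = InteractionEdgeList(edges=[("A", "B", "a", True), ("A", "B", "a", True),
                                       ("A", "B", "inh", True)])
        assert len(e) == 2


class TestDegrees:
    def test_hand_count(self):
        net = _net([("A", "B"), ("B", "A"), ("B", "C")])
        d = degrees(net).set_index("gene_id")
        assert d.loc["B", "indegree"] == 1
        assert d.loc["B", "outdegree"] == 2
        assert d.loc["B", "degree"] == 2

    def test_conservation(self):
        net = _net([("A", "B"), ("B", "C"), ("C", "A"), ("A", "C")])
        d = degrees(net)
        assert d["indegree"].sum() == d["outdegree"].sum() == net.graph.number_of_edges()

    def test_relabeling_invariance(self):
        net = _net([("A", "B"), ("B", "C"), ("C", "A")])
        mapping = {"A": "X", "B": "Y", "C": "Z"}
        g2 = nx.relabel_nodes(net.graph, mapping)
        net2 = SignalNetwork(graph=g2, styles={mapping[k]: v for k, v in net.styles.items()})
        d1 = degrees(net).set_index("gene_id")
        d2 = degrees(net2).set_index("gene_id")
        for old, new in mapping.items():
            assert (d1.loc[old] == d2.loc[new]).all()


class TestBetweenness:
    def test_directed_path(self):
        net = _net([("A", "B"), ("B", "C")])
        b = betweenness(net, mode="directed")
        assert b == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_undirected_star(self):
        net = _net([("C0", "L1"), ("C0", "L2"), ("C0", "L3")], undirected=True)
        b = betweenness(net, mode="undirected")
        assert b["C0"] == pytest.approx(1.0)
        assert all(b[leaf] == 0 for leaf in ("L1", "L2", "L3"))

    def test_off_path_node_zero(self):
        net = _net([("A", "B"), ("B", "C"), ("D", "A")])
        assert betweenness(net)["D"] == 0.0

    def test_small_network_zeros_with_warning(self, caplog):
        net = _net([("A", "B")])
        with caplog.at_level("WARNING"):
            b = betweenness(net)
        assert b == {"A": 0.0, "B": 0.0}
        assert "n=2" in caplog.text

    def test_matches_enumeration_oracle(self):
        worst = 0.0
        for g in random_directed_graphs(30, seed=123):
            net = SignalNetwork(graph=nx.DiGraph(g), styles={v: "up" for v in g.nodes})
            impl = betweenness(net, mode="directed")
            oracle = betweenness_enumeration(net.graph)
            worst = max(worst, max(abs(impl[v] - oracle[v]) for v in g.nodes))
        assert worst < 1e-9

    def test_oracle_equality_survives_node_removal(self):
        for g in random_directed_graphs(5, seed=77, n_max=10):
            g = nx.DiGraph(g)
            victim = sorted(g.nodes)[0]
            g.remove_node(victim)
            if g.number_of_nodes() < 3:
                continue
            net = SignalNetwork(graph=g, styles={v: "up" for v in g.nodes})
            impl = betweenness(net)
            oracle = betweenness_enumeration(g)
            assert max(abs(impl[v] - oracle[v]) for v in g.nodes) < 1e-9

    def test_directed_values_bounded_by_two(self):
        for g in random_directed_graphs(20, seed=5):
            net = SignalNetwork(graph=nx.DiGraph(g), styles={v: "up" for v in g.nodes})
            vals = list(betweenness(net, mode="directed").values())
            assert all(0.0 <= v <= 2.0 + 1e-12 for v in vals)
            und = betweenness(net, mode="undirected")
            assert all(0.0 <= v <= 1.0 + 1e-12 for v in und.values())


class TestClustering:
    def test_triangle(self):
        net = _net([("A", "B"), ("B", "C"), ("C", "A")])
        assert all(v == 1.0 for v in clustering_coefficient(net).values())

    def test_path_middle_zero(self):
        net = _net([("A", "B"), ("B", "C")])
        assert clustering_coefficient(net)["B"] == 0.0

    def test_four_cycle_with_chord(self):
        net = _net([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("A", "C")])
        c = clustering_coefficient(net)
        # chord endpoints A, C have 3 neighbors with 2 of 3 possible edges... by
        # hand: A's neighbors {B, C, D}; edges among them: B-C, C-D -> 2/3 pairs
        assert c["A"] == pytest.approx(2 / 3)
        assert c["C"] == pytest.approx(2 / 3)
        assert c["B"] == pytest.approx(1.0)  # neighbors {A, C} joined by the chord


class TestRankCoreGenes:
    def test_planted_hub_ranked_first(self, bundle):
        from rvmnet import run_de

        _, de_list, _ = run_de(bundle.matrix)
        net = build_signal_net(bundle.edges, de_list)
        core = rank_core_genes(net)
        assert core.iloc[0]["gene_id"] in bundle.truth.hub_genes

    def test_isolated_ties_broken_by_gene_id(self):
        net = _net([("B", "A"), ("D", "C")])  # two disjoint pairs: all betweenness 0
        core = rank_core_genes(net)
        assert (core["betweenness"] == 0).all()
        assert list(core["gene_id"]) == sorted(core["gene_id"])

    def test_output_covers_all_nodes(self):
        net = _net([("A", "B"), ("B", "C"), ("C", "A")])
        assert len(rank_core_genes(net)) == net.n
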