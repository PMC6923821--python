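import itertools

import networkx as nx
import numpy as np
import pytest

import oracles
from microsplit import (
    CorrEdge,
    CorrNetwork,
    DensityAssociation,
    SplitGraphModel,
    build_split_graph,
    enumerate_maximal_cliques,
    export_graphml,
    rank_cliques,
)
from microsplit.errors import ValidationError
from microsplit.splitgraph import write_cliques_tsv


def _net(edges, group="CDS"):
    corr = [CorrEdge(a, b, rho, 1e-5, 1e-4) for a, b, rho in edges]
    return CorrNetwork(group, "family", corr, (0.6, 0.05))


def _dens(taxon, module, density):
    n = 10
    k = round(density * n)
    return DensityAssociation(taxon, module, frozenset(f"K{i}" for i in range(k)),
                              n, density)


def _model(taxa, modules, clique_edges, cross_edges):
    return SplitGraphModel(frozenset(taxa), frozenset(modules),
                           list(clique_edges), list(cross_edges))


FIG4 = dict(
    net=_net([("f__Bacteroidaceae", "f__Lachnospiraceae", 0.94)]),
    dens=[_dens("f__Bacteroidaceae", "M00159", 0.89),
          _dens("f__Lachnospiraceae", "M00159", 0.67)],
)


class TestBuildSplitGraph:
    def test_two_taxa_one_module_configuration(self):
        g = build_split_graph(FIG4["net"], FIG4["dens"])
        assert len(g.taxon_nodes) == 2
        assert g.module_nodes == frozenset({"M00159"})
        assert len(g.clique_edges) == 1
        assert len(g.cross_edges) == 2

    def test_empty_density_list_reduces_to_correlation_network(self):
        g = build_split_graph(FIG4["net"], [])
        assert g.module_nodes == frozenset()
        assert g.n_edges == 1

    def test_isolated_taxon_with_cross_edge_retained(self):
        g = build_split_graph(FIG4["net"], [_dens("f__Veillonellaceae", "M1", 0.7)])
        assert "f__Veillonellaceae" in g.taxon_nodes

    def test_unknown_taxon_rejected_against_universe(self):
        with pytest.raises(ValidationError, match="Veillonellaceae"):
            build_split_graph(
                FIG4["net"], [_dens("f__Veillonellaceae", "M1", 0.7)],
                taxa_universe={"f__Bacteroidaceae", "f__Lachnospiraceae"},
            )

    def test_module_module_edges_impossible(self, rng):
        for _ in range(30):
            taxa, modules, ce, xe = oracles.random_split_graph_inputs(rng)
            g = _model(taxa, modules, ce, xe)
            nxg = g.to_networkx()
            for a, b in nxg.edges:
                classes = {nxg.nodes[a]["node_class"], nxg.nodes[b]["node_class"]}
                assert classes != {"module"}

    def test_overlapping_taxon_module_labels_rejected(self):
        with pytest.raises(ValidationError):
            build_split_graph(_net([("A", "M1", 0.9)]), [_dens("A", "M1", 0.7)])


class TestEnumerateMaximalCliques:
    def test_triangle_plus_fully_adjacent_module(self):
        g = _model(
            ["a", "b", "c"], ["M1"],
            [("a", "b", 0.8), ("a", "c", 0.7), ("b", "c", 0.9)],
            [("a", "M1", 0.7), ("b", "M1", 0.8), ("c", "M1", 0.9)],
        )
        cliques = enumerate_maximal_cliques(g)
        assert len(cliques) == 1
        (c,) = cliques
        assert c.taxa == frozenset({"a", "b", "c"}) and c.module == "M1"

    def test_module_adjacent_to_one_taxon_splits_cliques(self):
        g = _model(["t1", "t2"], ["M1"], [("t1", "t2", 0.8)], [("t1", "M1", 0.7)])
        members = {c.members for c in enumerate_maximal_cliques(g)}
        assert members == {frozenset({"t1", "t2"}), frozenset({"t1", "M1"})}

    def test_at_most_one_module_per_clique(self, rng):
        for _ in range(50):
            taxa, modules, ce, xe = oracles.random_split_graph_inputs(rng)
            g = _model(taxa, modules, ce, xe)
            for c in enumerate_maximal_cliques(g):
                n_modules = len(c.members) - len(c.taxa)
                assert n_modules <= 1

    def test_matches_exhaustive_enumeration_on_random_graphs(self, rng):
        for _ in range(60):
            taxa, modules, ce, xe = oracles.random_split_graph_inputs(rng)
            g = _model(taxa, modules, ce, xe)
            got = {c.members for c in enumerate_maximal_cliques(g)}
            edges = [(a, b) for a, b, _ in ce] + [(t, m) for t, m, _ in xe]
            expected = oracles.maximal_cliques_oracle(taxa + modules, edges)
            assert got == expected

    def test_taxa_only_granularity_flagged(self):
        g = _model(
            ["a", "b"], ["M1"],
            [("a", "b", 0.8)],
            [("a", "M1", 0.7), ("b", "M1", 0.9)],
        )
        mixed = enumerate_maximal_cliques(g)
        assert {c.members for c in mixed} == {frozenset({"a", "b", "M1"})}
        both = enumerate_maximal_cliques(g, include_taxa_only=True)
        kinds = {(c.kind, c.members) for c in both}
        assert ("taxa_only", frozenset({"a", "b"})) in kinds

    def test_relaxed_module_attachment_flag(self):
        g = _model(["t1", "t2"], ["M1"], [("t1", "t2", 0.8)], [("t1", "M1", 0.7)])
        relaxed = enumerate_maximal_cliques(g, module_attachment="any")
        assert {c.members for c in relaxed} == {frozenset({"t1", "t2", "M1"})}

    def test_completeness_and_maximality_verified_independently(self, rng):
        for _ in range(30):
            taxa, modules, ce, xe = oracles.random_split_graph_inputs(rng)
            g = _model(taxa, modules, ce, xe)
            nxg = g.to_networkx()
            for c in enumerate_maximal_cliques(g):
                members = sorted(c.members)
                for a, b in itertools.combinations(members, 2):
                    assert nxg.has_edge(a, b)
                for other in nxg.nodes:
                    if other in c.members:
                        continue
                    assert not all(nxg.has_edge(other, m) for m in members)


class TestRankCliques:
    def test_fig4_style_hand_sum(self):
        g = build_split_graph(FIG4["net"], FIG4["dens"])
        cliques = rank_cliques(enumerate_maximal_cliques(g), "sum")
        top = cliques[0]
        assert top.module == "M00159"
        assert top.weight == pytest.approx(0.94 + 0.89 + 0.67)
        assert top.weight == pytest.approx(2.50)

    def test_mean_of_single_edge_pair_is_its_rho(self):
        g = build_split_graph(_net([("a", "b", 0.7)]), [])
        (c,) = rank_cliques(enumerate_maximal_cliques(g), "mean")
        assert c.weight == pytest.approx(0.7)

    def test_negative_rho_contributes_magnitude(self):
        g = build_split_graph(_net([("a", "b", -0.66)]), [])
        (c,) = rank_cliques(enumerate_maximal_cliques(g), "sum")
        assert c.weight == pytest.approx(0.66)

    def test_deterministic_tie_breaking(self):
        g = _model(["a", "b", "c", "d"], [],
                   [("a", "b", 0.8), ("c", "d", 0.8)], [])
        order1 = [sorted(c.taxa) for c in rank_cliques(enumerate_maximal_cliques(g))]
        order2 = [sorted(c.taxa) for c in rank_cliques(enumerate_maximal_cliques(g))]
        assert order1 == order2 == [["a", "b"], ["c", "d"]]

    def test_top_k_truncates(self):
        g = _model(["a", "b", "c", "d"], [],
                   [("a", "b", 0.9), ("c", "d", 0.7)], [])
        cliques = rank_cliques(enumerate_maximal_cliques(g), top_k=1)
        assert len(cliques) == 1 and cliques[0].taxa == frozenset({"a", "b"})

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            rank_cliques([], scheme="median")


class TestExportGraphml:
    def test_fig4_configuration_round_trips(self, tmp_path):
        g = build_split_graph(FIG4["net"], FIG4["dens"])
        path = tmp_path / "g.graphml"
        cliques = rank_cliques(enumerate_maximal_cliques(g))
        export_graphml(g, cliques, path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 3
        assert back.number_of_edges() == 3
        classes = nx.get_node_attributes(back, "node_class")
        assert classes["M00159"] == "module"
        edge_classes = nx.get_edge_attributes(back, "edge_class")
        assert sorted(edge_classes.values()) == ["clique", "cross", "cross"]
        assert all(back.nodes[n]["cliques"] == "C1" for n in back.nodes)

    def test_empty_graph_is_valid_graphml(self, tmp_path):
        g = _model([], [], [], [])
        path = tmp_path / "empty.graphml"
        export_graphml(g, [], path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 0

    def test_negative_rho_sign_attribute(self, tmp_path):
        g = build_split_graph(_net([("a", "b", -0.66)]), [])
        path = tmp_path / "neg.graphml"
        export_graphml(g, None, path)
        back = nx.read_graphml(path)
        (data,) = [d for _, _, d in back.edges(data=True)]
        assert data["rho_sign"] == -1
        assert data["weight"] == pytest.approx(0.66)


def test_cliques_tsv_report(tmp_path):
    g = build_split_graph(FIG4["net"], FIG4["dens"])
    cliques = rank_cliques(enumerate_maximal_cliques(g))
    path = tmp_path / "cliques.tsv"
    write_cliques_tsv(cliques, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0].startswith("clique_id\t")
    assert len(lines) == 1 + len(cliques)
    assert "M00159" in lines[1]
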