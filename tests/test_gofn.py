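"""Term-overlap network construction and topology against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from mgnet import (
    EnrichmentRecord,
    GeneSet,
    GeneSetCollection,
    HypergeomInputs,
    build_gofn,
    dissect_term,
    node_betweenness,
    node_degree,
    pairwise_term_test,
)
from mgnet.errors import InputError, LookupError_
from mgnet.gofn import TermNetwork

from _oracles import brute_force_gofn_edges, comb_upper_tail, path_enum_betweenness


def record(term, genes_n, p=1e-6):
    return EnrichmentRecord(
        term=term, name=term,
        inputs=HypergeomInputs(x=5, M=1000, K=genes_n, N=50),
        overlap_genes=frozenset(), p=p, q=p, significant=True,
    )


class TestPairwiseTest:
    def test_disjoint_sets(self):
        x, p = pairwise_term_test({"A", "B"}, {"C"}, M=100)
        assert (x, p) == (0, 1.0)

    def test_identical_sets_tiny_p(self):
        genes = {f"G{i}" for i in range(5)}
        x, p = pairwise_term_test(genes, set(genes), M=100)
        assert x == 5
        assert p == pytest.approx(comb_upper_tail(5, 100, 5, 5), rel=1e-9)

    def test_worked_example_and_symmetry(self):
        a = {"G1", "G2", "G3", "G4"}
        b = {"G1", "G2", "G3", "G5", "G6"}
        assert pairwise_term_test(a, b, 10)[1] == pytest.approx(11 / 42, abs=1e-12)
        assert pairwise_term_test(a, b, 10) == pairwise_term_test(b, a, 10)

    def test_set_larger_than_universe_raises(self):
        with pytest.raises(InputError):
            pairwise_term_test({f"G{i}" for i in range(11)}, {"G1"}, M=10)


class TestBuildGofn:
    def test_disjoint_terms_no_edges(self):
        annot = GeneSetCollection(
            [
                GeneSet(f"GO:{i}", f"t{i}", frozenset(f"G{i}{j}" for j in range(10)))
                for i in range(3)
            ]
        )
        universe = annot.all_genes() | {f"U{i}" for i in range(100)}
        net = build_gofn([record(f"GO:{i}", 10) for i in range(3)], annot, universe)
        assert net.n_nodes == 3 and net.n_edges == 0

    def test_identical_terms_one_strong_edge(self):
        genes = frozenset(f"G{i:03d}" for i in range(20))
        annot = GeneSetCollection(
            [GeneSet("GO:A", "a", genes), GeneSet("GO:B", "b", genes)]
        )
        universe = {f"G{i:03d}" for i in range(1000)}
        net = build_gofn([record("GO:A", 20), record("GO:B", 20)], annot, universe)
        assert net.n_edges == 1
        edge = net.graph.edges["GO:A", "GO:B"]
        assert edge["x"] == 20 and edge["q"] < 0.05
        assert edge["shared_genes"] == genes

    def test_matches_brute_force_on_seeded_terms(self):
        """30 random overlapping terms: edge set equals the naive loop."""
        rng = np.random.default_rng(42)
        universe_list = [f"G{i:04d}" for i in range(800)]
        gene_sets = {}
        entries = []
        for i in range(30):
            size = int(rng.integers(10, 40))
            pool = universe_list[:200] if i % 2 else universe_list
            genes = frozenset(rng.choice(pool, size=size, replace=False).tolist())
            gene_sets[f"GO:{i:02d}"] = set(genes)
            entries.append(GeneSet(f"GO:{i:02d}", f"t{i}", genes))
        annot = GeneSetCollection(entries)
        universe = set(universe_list)
        net = build_gofn(
            [record(t, len(gene_sets[t])) for t in sorted(gene_sets)], annot, universe
        )
        expected = brute_force_gofn_edges(gene_sets, len(universe), 0.05)
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == expected and expected  # non-trivial fixture

    def test_edge_count_invariant_to_term_order(self):
        rng = np.random.default_rng(3)
        universe_list = [f"G{i:04d}" for i in range(500)]
        entries = [
            GeneSet(
                f"GO:{i}", f"t{i}",
                frozenset(rng.choice(universe_list[:150], size=25, replace=False).tolist()),
            )
            for i in range(10)
        ]
        annot = GeneSetCollection(entries)
        recs = [record(e.set_id, 25) for e in entries]
        a = build_gofn(recs, annot, set(universe_list))
        b = build_gofn(list(reversed(recs)), annot, set(universe_list))
        assert a.n_edges == b.n_edges


class TestTopology:
    @staticmethod
    def _net(edges, nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            g.add_edge(a, b, shared_risk_genes=frozenset())
        return TermNetwork(graph=g, fdr=0.05)

    def test_path_degrees_and_betweenness(self):
        net = self._net([("A", "B"), ("B", "C")])
        assert node_degree(net).tolist() == [1, 2, 1]
        bw = node_betweenness(net)
        assert bw["B"] == 1.0 and bw["A"] == 0.0 and bw["C"] == 0.0

    def test_isolated_node_zero_degree(self):
        net = self._net([("A", "B")], nodes=["Z"])
        assert node_degree(net)["Z"] == 0

    def test_handshake_identity(self):
        rng = np.random.default_rng(0)
        g = nx.gnm_random_graph(30, 100, seed=1)
        net = TermNetwork(graph=g, fdr=0.05)
        assert node_degree(net).sum() == 200

    def test_triangle_betweenness_zero(self):
        net = self._net([("A", "B"), ("B", "C"), ("C", "A")])
        assert (node_betweenness(net) == 0).all()

    def test_star_center_formula(self):
        k = 6
        net = self._net([("HUB", f"L{i}") for i in range(k)])
        assert node_betweenness(net)["HUB"] == k * (k - 1) / 2
        leaves = node_betweenness(net).drop("HUB")
        assert (leaves == 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_path_enumeration_oracle(self, seed):
        """10-node random graphs vs explicit shortest-path enumeration."""
        g = nx.gnp_random_graph(10, 0.35, seed=seed)
        net = TermNetwork(graph=g, fdr=0.05)
        got = node_betweenness(net)
        want = path_enum_betweenness(list(g.edges), set(g.nodes))
        for node in g.nodes:
            assert got[node] == pytest.approx(want[node], abs=1e-9)

    def test_raw_counts_mode_on_square(self):
        # C4: two shortest paths between opposite corners; fractional gives
        # 0.5 per interior node, raw counts give 1.
        net = self._net([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        assert node_betweenness(net)["B"] == 0.5
        assert node_betweenness(net, mode="raw-counts")["B"] == 1.0


class TestDissect:
    @staticmethod
    def _star():
        g = nx.Graph()
        g.add_edge("F", "N1", shared_risk_genes=frozenset({"TNF"}))
        g.add_edge("F", "N2", shared_risk_genes=frozenset({"IL6", "TNF"}))
        g.add_edge("F", "N3", shared_risk_genes=frozenset())
        return TermNetwork(graph=g, fdr=0.05)

    def test_isolated_focus(self):
        g = nx.Graph()
        g.add_node("F")
        d = dissect_term(TermNetwork(graph=g, fdr=0.05), "F")
        assert d.neighbors_via_risk == [] and d.neighbors_without_risk == []
        assert d.subnetwork.number_of_nodes() == 1

    def test_partition_and_risk_union(self):
        d = dissect_term(self._star(), "F")
        assert d.neighbors_via_risk == ["N1", "N2"]
        assert d.neighbors_without_risk == ["N3"]
        assert d.risk_genes_on_edges == {"TNF", "IL6"}

    def test_unknown_focus_raises(self):
        with pytest.raises(LookupError_):
            dissect_term(self._star(), "MISSING")
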