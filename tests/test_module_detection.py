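"""Detector correctness against brute-force oracles and planted-module recovery."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modflow.differential_analysis import DifferentialTable, differential_table
from modflow.io_formats import GeneNetwork
from modflow.module_detection import (
    detect_clique_sum,
    detect_coexpression,
    detect_diamond,
    enumerate_maximal_cliques,
)
from modflow.synthetic_data import SimulationConfig, generate_network, generate_omics
from tests.conftest import make_matrix


def graph_from_edges(edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, score=900)
    return GeneNetwork(g)


def brute_force_maximal_cliques(graph, min_size):
    """Power-set oracle: check every vertex subset for maximal completeness."""
    nodes = list(graph.nodes)
    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if all(graph.has_edge(u, v) for u, v in combinations(subset, 2)):
                is_maximal = not any(
                    all(graph.has_edge(w, u) for u in subset)
                    for w in nodes
                    if w not in subset
                )
                if is_maximal:
                    cliques.append(tuple(sorted(subset)))
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def diff_table_from_p(pvals):
    genes = sorted(pvals)
    p = np.array([pvals[g] for g in genes])
    order = np.lexsort((genes, p))
    rank = np.empty(len(p), int)
    rank[order] = np.arange(1, len(p) + 1)
    return DifferentialTable(
        pd.DataFrame(
            {"effect": np.zeros(len(p)), "t": np.zeros(len(p)), "p": p,
             "p_adj": np.minimum(1.0, p * len(p)), "rank": rank},
            index=genes,
        )
    )


class TestEnumerateMaximalCliques:
    def test_triangle_with_pendant_edge(self):
        net = graph_from_edges([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        assert enumerate_maximal_cliques(net, min_size=2) == [("A", "B", "C"), ("C", "D")]

    def test_complete_graph_is_single_clique(self):
        net = graph_from_edges(combinations("ABCD", 2))
        assert enumerate_maximal_cliques(net, min_size=3) == [("A", "B", "C", "D")]

    def test_edgeless_graph_empty(self):
        assert enumerate_maximal_cliques(GeneNetwork(nx.Graph()), min_size=3) == []

    def test_max_cliques_guard(self):
        net = graph_from_edges(combinations("ABCDEFG", 2))
        with pytest.raises(ValueError, match="score threshold"):
            enumerate_maximal_cliques(net, min_size=2, max_cliques=0)

    def test_equals_power_set_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(4, 13))
            p = rng.uniform(0.2, 0.7)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            for u, v in g.edges:
                g[u][v]["score"] = 901
            net = GeneNetwork(g)
            assert enumerate_maximal_cliques(net, min_size=2) == brute_force_maximal_cliques(
                g, min_size=2
            )


class TestDetectCliqueSum:
    def test_perfect_clique_recovery(self):
        config = SimulationConfig(
            n_genes=150, module_size=10, background_edge_prob=0.02,
            perfect_clique=True, effect_size=2.5, n_case=20, n_control=20,
            risk_set_size=30,
        )
        recovered = 0
        for seed in range(10):
            net, truth = generate_network(config, seed=seed)
            matrix = generate_omics(truth, config, "expression", seed=seed + 500)
            module, _ = detect_clique_sum(net, differential_table(matrix))
            if truth.module <= module.genes:
                recovered += 1
        assert recovered >= 9

    def test_no_seed_in_any_clique_gives_empty_module(self):
        net = graph_from_edges([("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y")])
        table = diff_table_from_p({"X": 0.001, "Y": 0.9, "A": 0.8, "B": 0.85, "C": 0.95})
        module, report = detect_clique_sum(net, table, seed_fraction=0.2)
        assert module.genes == frozenset()

    def test_diff_table_row_order_invariance(self, small_study):
        net = small_study.network
        table = differential_table(small_study.expression[0])
        shuffled = DifferentialTable(table.table.sample(frac=1, random_state=0))
        m1, _ = detect_clique_sum(net, table)
        m2, _ = detect_clique_sum(net, shuffled)
        assert m1.genes == m2.genes

    def test_provenance_tag(self, small_study):
        module, _ = detect_clique_sum(
            small_study.network, differential_table(small_study.expression[0])
        )
        assert module.method == "clique_sum"

    def test_report_invariants(self, small_study):
        _, report = detect_clique_sum(
            small_study.network, differential_table(small_study.expression[0])
        )
        t = report.table
        assert (t["p_adj"] + 1e-12 >= t["p"]).all()
        assert (t["size"] >= 3).all()


class TestDetectDiamond:
    def test_zero_iterations_returns_seeds_in_network(self):
        net = graph_from_edges([("A", "B"), ("B", "C")])
        module = detect_diamond(net, frozenset({"A", "Z"}), n_iterations=0)
        assert module.genes == {"A"}

    def test_star_tie_breaks_lexicographically(self):
        net = graph_from_edges([("HUB", leaf) for leaf in ("L4", "L2", "L3", "L1")])
        module = detect_diamond(net, frozenset({"HUB"}), n_iterations=1)
        assert module.added_order == ("L1",)

    def test_grows_one_gene_per_iteration(self):
        net, truth = generate_network(
            SimulationConfig(n_genes=100, module_size=10, background_edge_prob=0.05),
            seed=3,
        )
        seeds = frozenset(list(truth.module)[:3])
        sizes = [len(detect_diamond(net, seeds, n_iterations=k)) for k in range(5)]
        assert sizes == [len(seeds & net.nodes) + k for k in range(5)]

    def test_no_seed_in_network_rejected(self):
        net = graph_from_edges([("A", "B")])
        with pytest.raises(ValueError):
            detect_diamond(net, frozenset({"Z"}))

    def test_greedy_step_equals_brute_force_scan(self):
        # each choice minimises the hypergeometric tail over all candidates
        rng = np.random.default_rng(9)
        for trial in range(20):
            n = int(rng.integers(10, 51))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            for u, v in g.edges:
                g[u][v]["score"] = 901
            if g.number_of_edges() == 0:
                continue
            net = GeneNetwork(g)
            seeds = frozenset(sorted(g.nodes)[:3]) & set(g.nodes)
            module = detect_diamond(net, seeds, n_iterations=5)
            # replay: verify each recorded addition against an exhaustive scan
            members = set(seeds) & set(g.nodes)
            n_nodes = g.number_of_nodes()
            for gene_added in module.added_order:
                best = None
                for cand in sorted(set(g.nodes) - members):
                    k = sum(1 for nb in g.neighbors(cand) if nb in members)
                    if k == 0:
                        continue
                    p = stats.hypergeom.sf(k - 1, n_nodes, len(members), g.degree(cand))
                    key = (p, -k, cand)
                    if best is None or key < best:
                        best = key
                assert best is not None and best[2] == gene_added
                members.add(gene_added)


class TestDetectCoexpression:
    def _blocks_matrix(self, seed, n_samples=30):
        """Two correlated blocks of 15 genes + 20 noise genes."""
        rng = np.random.default_rng(seed)
        shared1 = rng.normal(size=n_samples)
        shared2 = rng.normal(size=n_samples)
        rows = []
        for _ in range(15):
            rows.append(shared1 * 0.9 + rng.normal(scale=np.sqrt(1 - 0.81), size=n_samples))
        for _ in range(15):
            rows.append(shared2 * 0.9 + rng.normal(scale=np.sqrt(1 - 0.81), size=n_samples))
        for _ in range(20):
            rows.append(rng.normal(size=n_samples))
        genes = [f"B1_{i}" for i in range(15)] + [f"B2_{i}" for i in range(15)] + [
            f"N_{i}" for i in range(20)
        ]
        return make_matrix(np.array(rows), genes=genes)

    def test_recovers_flagged_block(self):
        jaccards = []
        for seed in range(10):
            matrix = self._blocks_matrix(seed)
            block1 = {f"B1_{i}" for i in range(15)}
            # flag block-1 genes as differential
            pvals = {g: (0.001 if g in block1 else 0.5) for g in matrix.features}
            module = detect_coexpression(matrix, diff_table_from_p(pvals))
            inter = len(module.genes & block1)
            union = len(module.genes | block1)
            jaccards.append(inter / union)
        assert np.median(jaccards) >= 0.8

    def test_deterministic(self):
        matrix = self._blocks_matrix(3)
        pvals = {g: 0.5 for g in matrix.features}
        pvals["B1_0"] = 0.001
        m1 = detect_coexpression(matrix, diff_table_from_p(pvals))
        m2 = detect_coexpression(matrix, diff_table_from_p(pvals))
        assert m1.genes == m2.genes

    def test_independent_noise_rarely_enriched(self):
        # under pure noise the chosen cluster's seed enrichment stays null
        n_enriched = 0
        n_trials = 30
        for seed in range(n_trials):
            rng = np.random.default_rng(1000 + seed)
            matrix = make_matrix(rng.normal(size=(40, 20)))
            pvals = {g: rng.uniform() for g in matrix.features}
            module = detect_coexpression(matrix, diff_table_from_p(pvals), min_module_size=5)
            if module.genes:
                seeds = set(
                    sorted(pvals, key=pvals.get)[: int(np.ceil(0.05 * len(pvals)))]
                )
                k = len(module.genes & seeds)
                p = stats.hypergeom.sf(k - 1, 40, len(seeds), len(module.genes))
                if p < 0.05:
                    n_enriched += 1
        assert n_enriched <= 0.1 * n_trials + 2

    def test_all_constant_genes_gives_empty_module(self):
        matrix = make_matrix(np.ones((12, 6)))
        pvals = {g: 0.5 for g in matrix.features}
        module = detect_coexpression(matrix, diff_table_from_p(pvals))
        assert module.genes == frozenset()
        assert module.method == "coexpression"
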