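"""Disease-module detection on gene interaction networks.

Three exemplar algorithms, one per algorithm class:

* **clique-based** (:func:`detect_clique_sum`) — enumerate maximal cliques,
  score each for seed-gene enrichment with a one-sided hypergeometric test,
  correct across cliques with Benjamini–Hochberg, and return the union of
  significant cliques.  This reconstructs "differentially expressed clique"
  scoring from its public description: maximal cliques are small fully
  connected building blocks of the interactome, and a clique crowded with
  differential seed genes is a disease-module candidate.
* **seed-based** (:func:`detect_diamond`) — the DIAMOnD greedy expansion:
  repeatedly add the candidate gene whose number of links into the current
  member set is most significant under a hypergeometric model of random
  wiring.
* **co-expression-based** (:func:`detect_coexpression`) — a signed
  correlation adjacency raised to a soft-threshold power, average-linkage
  hierarchical clustering, a sweep of cut heights, and selection of the
  cluster most enriched for differential seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from modflow.differential_analysis import (
    DifferentialTable,
    benjamini_hochberg,
    select_seed_genes,
)
from modflow.io_formats import GeneNetwork, Module, OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CliqueReport",
    "enumerate_maximal_cliques",
    "detect_clique_sum",
    "detect_diamond",
    "detect_coexpression",
]


@dataclass(frozen=True)
class CliqueReport:
    """Per-clique seed-enrichment scores."""

    table: pd.DataFrame  # columns: clique (tuple), size, n_seeds, p, p_adj, significant

    def __len__(self) -> int:
        return len(self.table)


def enumerate_maximal_cliques(
    network: GeneNetwork, min_size: int = 3, max_cliques: int = 2_000_000
) -> list[tuple[str, ...]]:
    """All maximal cliques of size >= ``min_size``.

    Each clique is returned sorted lexicographically; the list is sorted by
    (size descending, lexicographic).  Raises if more than ``max_cliques``
    maximal cliques are found, advising a higher score threshold.
    """
    cliques: list[tuple[str, ...]] = []
    n_seen = 0
    for clique in nx.find_cliques(network.graph):
        n_seen += 1
        if n_seen > max_cliques:
            raise ValueError(
                f"more than {max_cliques} maximal cliques; "
                "raise the network score threshold to sparsify the graph"
            )
        if len(clique) >= min_size:
            cliques.append(tuple(sorted(clique)))
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def detect_clique_sum(
    network: GeneNetwork,
    diff_table: DifferentialTable,
    seed_fraction: float = 0.05,
    min_clique_size: int = 3,
    clique_alpha: float = 0.01,
    max_cliques: int = 2_000_000,
) -> tuple[Module, CliqueReport]:
    """Clique-based module: union of seed-enriched maximal cliques.

    Each maximal clique is tested with a one-sided hypergeometric test
    (clique as the draw, network genes as the universe, seed genes as
    successes); p-values are BH-corrected across cliques and the module is
    the union of cliques with adjusted p < ``clique_alpha``.
    """
    seeds = select_seed_genes(diff_table, network, seed_fraction).genes
    cliques = enumerate_maximal_cliques(network, min_clique_size, max_cliques)
    n_universe = network.n_nodes
    n_seeds_total = len(seeds & network.nodes)
    if not cliques:
        empty = Module(frozenset(), method="clique_sum")
        report = CliqueReport(
            pd.DataFrame(columns=["clique", "size", "n_seeds", "p", "p_adj", "significant"])
        )
        return empty, report
    sizes = np.array([len(c) for c in cliques])
    n_hits = np.array([len(seeds.intersection(c)) for c in cliques])
    # P(X >= n_hits) for X ~ Hypergeom(N=universe, K=seeds, n=clique size)
    p = stats.hypergeom.sf(n_hits - 1, n_universe, n_seeds_total, sizes)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p_adj = benjamini_hochberg(p)
    significant = p_adj < clique_alpha
    genes: set[str] = set()
    for clique, sig in zip(cliques, significant):
        if sig:
            genes.update(clique)
    report = CliqueReport(
        pd.DataFrame(
            {
                "clique": cliques,
                "size": sizes,
                "n_seeds": n_hits,
                "p": p,
                "p_adj": p_adj,
                "significant": significant,
            }
        )
    )
    return Module(frozenset(genes), method="clique_sum"), report


def _diamond_pvalue(n_links: int, degree: int, n_members: int, n_nodes: int) -> float:
    """Hypergeometric tail P(X >= n_links) for a candidate of given degree."""
    return float(stats.hypergeom.sf(n_links - 1, n_nodes, n_members, degree))


def detect_diamond(
    network: GeneNetwork, seeds: frozenset[str] | set[str], n_iterations: int = 200
) -> Module:
    """DIAMOnD seed expansion without seed weighting.

    At each step the non-member node with the smallest hypergeometric tail
    probability of its link count into the current member set joins the
    module.  Ties break by more links to members, then by lexicographically
    smaller symbol.  The returned module is (seeds ∩ network) plus all
    added genes; the addition order is recorded on ``Module.added_order``.
    """
    g = network.graph
    members = set(seeds) & set(g.nodes)
    if not members:
        raise ValueError("no seed gene is present in the network")
    n_nodes = g.number_of_nodes()
    # candidate -> number of links into the member set, maintained incrementally
    links: dict[str, int] = {}
    for m in members:
        for nb in g.neighbors(m):
            if nb not in members:
                links[nb] = links.get(nb, 0) + 1
    added: list[str] = []
    for _ in range(n_iterations):
        if not links:
            break
        best_gene = None
        best_key: tuple[float, int, str] | None = None
        n_members = len(members)
        for gene, k in links.items():
            p = _diamond_pvalue(k, g.degree(gene), n_members, n_nodes)
            key = (p, -k, gene)
            if best_key is None or key < best_key:
                best_key = key
                best_gene = gene
        assert best_gene is not None
        members.add(best_gene)
        added.append(best_gene)
        del links[best_gene]
        for nb in g.neighbors(best_gene):
            if nb not in members:
                links[nb] = links.get(nb, 0) + 1
    return Module(frozenset(members), method="diamond", added_order=tuple(added))


def detect_coexpression(
    matrix: OmicsMatrix,
    diff_table: DifferentialTable,
    power: int = 6,
    n_height_steps: int = 20,
    min_module_size: int = 10,
    seed_fraction: float = 0.05,
) -> Module:
    """Co-expression module via signed adjacency and hierarchical clustering.

    Signed adjacency a_ij = ((1 + cor_ij) / 2)^power over all samples,
    dissimilarity 1 - a, average linkage.  ``n_height_steps`` evenly spaced
    cut heights are swept; the cut maximising the number of clusters of
    size >= ``min_module_size`` wins, and among its clusters the one with
    the smallest one-sided hypergeometric seed-enrichment p is returned.
    Constant genes are removed first; if fewer than ``min_module_size``
    genes remain the empty module is returned with a warning.
    """
    if matrix.values.shape[1] < 4:
        raise ValueError("need >= 4 samples for co-expression analysis")
    values = matrix.values
    keep = values.std(axis=1) > 0
    if (~keep).any():
        logger.info("removing %d constant genes", int((~keep).sum()))
    values = values.loc[keep]
    if len(values) < min_module_size:
        logger.warning("fewer than %d non-constant genes; empty module", min_module_size)
        return Module(frozenset(), method="coexpression")
    genes = list(values.index)
    cor = np.corrcoef(values.to_numpy(float))
    adjacency = ((1.0 + cor) / 2.0) ** power
    dissim = 1.0 - adjacency
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    heights = link[:, 2]
    cut_grid = np.linspace(heights.min(), heights.max(), n_height_steps)
    best_cut_labels = None
    best_n_big = -1
    for h in cut_grid:
        labels = hierarchy.fcluster(link, t=h, criterion="distance")
        counts = np.bincount(labels)
        n_big = int((counts >= min_module_size).sum())
        if n_big > best_n_big:  # first (lowest) height wins ties
            best_n_big = n_big
            best_cut_labels = labels
    if best_cut_labels is None or best_n_big == 0:
        return Module(frozenset(), method="coexpression")
    seeds = select_seed_genes(diff_table, genes, seed_fraction).genes
    n_universe = len(genes)
    n_seed = len(seeds)
    gene_arr = np.asarray(genes, dtype=object)
    best_p = np.inf
    best_cluster: frozenset[str] = frozenset()
    for label in np.unique(best_cut_labels):
        cluster = frozenset(gene_arr[best_cut_labels == label])
        if len(cluster) < min_module_size:
            continue
        n_hit = len(cluster & seeds)
        p = float(stats.hypergeom.sf(n_hit - 1, n_universe, n_seed, len(cluster)))
        if p < best_p or (p == best_p and sorted(cluster) < sorted(best_cluster)):
            best_p = p
            best_cluster = cluster
    return Module(best_cluster, method="coexpression")
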