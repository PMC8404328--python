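"""Cross-cutting benchmark and validation statistics.

Everything the benchmark reports beyond raw module p-values lives here:

* Fisher's method meta-p-values for ranking methods and datasets;
* exact binomial excess-significance tests (is the number of significant
  modules larger than the alpha-level expectation?);
* Spearman confound diagnostics of the enrichment metric against module
  size and interactome betweenness centrality, with the t-approximation
  for significance;
* Fisher's exact enrichment of a module in a gene set over a universe,
  with the cross-product odds ratio (Haldane–Anscombe +0.5 only when a
  zero cell occurs, flagged in the result);
* a permutation overlap test with its analytic hypergeometric twin (the
  analytic tail is reported alongside because a Monte-Carlo p cannot
  resolve extreme tails);
* pairwise overlap odds ratios between named gene lists with group means;
* the method × dataset benchmark table with meta-p ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from modflow.io_formats import GeneNetwork, Module
from modflow.gwas_scoring import ModuleScore

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "BenchmarkTable",
    "fisher_meta_p",
    "binomial_excess_p",
    "spearman_rho_p",
    "rho_to_p",
    "fisher_exact_enrichment",
    "overlap_permutation_p",
    "pairwise_overlap_or",
    "module_centrality",
    "build_benchmark_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """2×2 overlap table with odds ratio and exact p-values.

    Cells: ``a`` in both sets, ``b`` in A only, ``c`` in B only, ``d`` in
    neither; a + b + c + d equals the universe size.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_one_sided: float
    p_two_sided: float
    haldane_corrected: bool = False

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class BenchmarkTable:
    """Module p-values by (method, dataset) with meta-p ranks."""

    pvalues: pd.DataFrame  # methods × datasets, NaN = missing (empty module)
    method_meta_p: pd.Series
    dataset_meta_p: pd.Series
    method_rank: pd.Series
    dataset_rank: pd.Series
    n_missing: int


def fisher_meta_p(ps: Sequence[float]) -> float:
    """Fisher's method: X = -2 Σ ln p ~ χ²(2k) under the joint null."""
    p = np.asarray(ps, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(np.clip(stats.chi2.sf(x, df=2 * p.size), np.finfo(float).tiny, 1.0))


def binomial_excess_p(k_significant: int, n_tests: int, alpha0: float = 0.05) -> float:
    """Exact upper-tail P(X >= k) for X ~ Binomial(n, alpha0).

    Measures whether more tests reached significance than the alpha-level
    expectation under independence.
    """
    if not 0 < alpha0 < 1:
        raise ValueError(f"alpha0 must lie in (0, 1), got {alpha0}")
    if not 0 <= k_significant <= n_tests:
        raise ValueError("need 0 <= k <= n")
    if k_significant == 0:
        return 1.0
    return float(stats.binom.sf(k_significant - 1, n_tests, alpha0))


def rho_to_p(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via the t-approximation.

    t = rho * sqrt((n - 2) / (1 - rho²)) on n - 2 degrees of freedom.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1 <= rho <= 1:
        raise ValueError("rho must lie in [-1, 1]")
    if abs(rho) == 1:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_rho_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Midrank Spearman correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need two equal-length vectors with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    return rho, rho_to_p(rho, x.size)


def fisher_exact_enrichment(
    set_a: set[str] | frozenset[str],
    set_b: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
) -> EnrichmentResult:
    """Fisher's exact test of the overlap of two gene sets over a universe.

    One-sided p is the enrichment (upper) tail; the odds ratio is the
    cross-product a·d / (b·c), with the Haldane–Anscombe +0.5 correction
    applied (and flagged) only when a zero cell occurs.
    """
    if not universe:
        raise ValueError("empty universe")
    set_a = frozenset(set_a) & frozenset(universe)
    set_b = frozenset(set_b) & frozenset(universe)
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    p_two = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    p_one = float(stats.fisher_exact(table, alternative="greater").pvalue)
    haldane = min(a, b, c, d) == 0
    if haldane:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return EnrichmentResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=float(odds),
        p_one_sided=float(np.clip(p_one, np.finfo(float).tiny, 1.0)),
        p_two_sided=float(np.clip(p_two, np.finfo(float).tiny, 1.0)),
        haldane_corrected=haldane,
    )


def overlap_permutation_p(
    module: set[str] | frozenset[str],
    gene_set: set[str] | frozenset[str],
    universe: Sequence[str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test of module/gene-set overlap, with analytic twin.

    Null: overlaps of ``n_permutations`` uniform same-size draws from the
    universe.  Empirical p = (#{null >= observed} + 1) / (B + 1).  The
    analytic twin is the one-sided hypergeometric tail, reported alongside
    for tails beyond Monte-Carlo resolution.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    universe = sorted(set(universe))
    module = frozenset(module)
    if not module <= set(universe):
        raise ValueError("module must be a subset of the universe")
    gene_set = frozenset(gene_set) & set(universe)
    observed = len(module & gene_set)
    rng = np.random.default_rng(seed)
    uni = np.asarray(universe, dtype=object)
    in_set = np.isin(uni, sorted(gene_set))
    k = len(module)
    # vectorised sampling without replacement: k smallest random keys per
    # row, in chunks to bound memory
    n = len(uni)
    chunk = max(1, 20_000_000 // n)
    parts = []
    for start in range(0, n_permutations, chunk):
        rows = min(chunk, n_permutations - start)
        keys = rng.random((rows, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        parts.append(in_set[idx].sum(axis=1))
    null = np.concatenate(parts)
    p_emp = (np.count_nonzero(null >= observed) + 1) / (n_permutations + 1)
    p_analytic = float(
        stats.hypergeom.sf(observed - 1, len(universe), len(gene_set), k)
    )
    return float(p_emp), float(np.clip(p_analytic, np.finfo(float).tiny, 1.0))


def pairwise_overlap_or(
    lists: Mapping[str, set[str] | frozenset[str]],
    universe: Sequence[str],
    groups: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Haldane-corrected overlap odds ratios for every unordered list pair.

    Returns a table with one row per pair (names, group label, 2×2 counts,
    OR) and the mean OR per group label.  With a ``groups`` map the pair
    label is ``within:<g>`` when both members share group ``g`` and
    ``across`` otherwise; without one, all pairs are labelled ``all``.
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    uni = frozenset(universe)
    for name, genes in lists.items():
        if not frozenset(genes) <= uni:
            raise ValueError(f"list {name!r} is not a subset of the universe")
    rows = []
    for name_a, name_b in combinations(sorted(lists), 2):
        ga, gb = frozenset(lists[name_a]), frozenset(lists[name_b])
        a = len(ga & gb)
        b = len(ga - gb)
        c = len(gb - ga)
        d = len(uni) - a - b - c
        if min(a, b, c, d) == 0:
            odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            odds = a * d / (b * c)
        if groups is None:
            label = "all"
        else:
            label = (
                f"within:{groups[name_a]}" if groups[name_a] == groups[name_b] else "across"
            )
        rows.append(
            {"list_a": name_a, "list_b": name_b, "pair_group": label,
             "a": a, "b": b, "c": c, "d": d, "odds_ratio": float(odds)}
        )
    table = pd.DataFrame(rows)
    means = table.groupby("pair_group")["odds_ratio"].mean().to_dict()
    return table, means


def module_centrality(network: GeneNetwork, module: Module | set[str]) -> float:
    """Mean normalised shortest-path betweenness over the module's genes.

    Module genes absent from the network are dropped with a warning; an
    entirely absent module is an error.
    """
    genes = module.genes if isinstance(module, Module) else frozenset(module)
    present = genes & network.nodes
    dropped = len(genes) - len(present)
    if dropped:
        logger.warning("%d module genes absent from network dropped", dropped)
    if not present:
        raise ValueError("no module gene is present in the network")
    centrality = nx.betweenness_centrality(network.graph, normalized=True)
    return float(np.mean([centrality[g] for g in sorted(present)]))


def build_benchmark_table(
    scores: Sequence[tuple[str, str, ModuleScore | None]],
) -> BenchmarkTable:
    """Method × dataset p-value matrix with Fisher meta-p ranks.

    ``scores`` holds (method, dataset, score-or-None) records; None marks
    an empty module, which is excluded from meta-p and counted in
    ``n_missing``.  Both margins are ranked ascending by meta-p.
    """
    records = [
        {"method": m, "dataset": d, "p": s.p_analytic if s is not None else np.nan}
        for m, d, s in scores
    ]
    if not records or all(np.isnan(r["p"]) for r in records):
        raise ValueError("all benchmark cells are missing")
    df = pd.DataFrame(records)
    pivot = df.pivot_table(index="method", columns="dataset", values="p", dropna=False)
    pivot = pivot.sort_index(axis=0).sort_index(axis=1)
    n_missing = int(pivot.isna().sum().sum())

    def _meta(row: pd.Series) -> float:
        ps = row.dropna().to_numpy()
        return fisher_meta_p(ps) if ps.size else np.nan

    method_meta = pivot.apply(_meta, axis=1)
    dataset_meta = pivot.apply(_meta, axis=0)
    method_rank = method_meta.rank(method="first", ascending=True).astype("Int64")
    dataset_rank = dataset_meta.rank(method="first", ascending=True).astype("Int64")
    return BenchmarkTable(
        pvalues=pivot,
        method_meta_p=method_meta,
        dataset_meta_p=dataset_meta,
        method_rank=method_rank,
        dataset_rank=dataset_rank,
        n_missing=n_missing,
    )
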