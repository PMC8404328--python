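"""Pascal-style gene and module scoring from GWAS summary statistics.

SNP association p-values are mapped to the closest gene within a window
around the gene body, fused into a gene-level p-value, and gene scores of a
module are fused into a chi-square statistic whose upper-tail probability
is the module's genomic-concordance significance.

Gene-score variants (both exposed; ``sidak_min`` is the default):

* ``sidak_min`` — 1 - (1 - min p)^K over the gene's K SNPs, the "max"
  statistic with a Šidák correction for the number of SNPs tested;
* ``sum_chi2`` — sum the chi-square(1) quantiles of 1 - p over SNPs and
  evaluate the chi-square(K) upper tail, the "sum" statistic.

Module fusion: T = Σ_g Q_{χ²(1)}(1 - p_g) over the k scored module genes,
p = upper tail of χ²(k) at T.  SNPs (and hence gene scores) are treated as
independent: the simulator generates no linkage disequilibrium, and
LD-aware decorrelation against a reference panel is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from modflow.io_formats import GeneCoordinates, GwasSummary, Module

logger = logging.getLogger(__name__)

__all__ = [
    "GeneScoreTable",
    "ModuleScore",
    "map_snps_to_genes",
    "gene_score",
    "gene_score_table",
    "score_module_analytic",
    "score_module_empirical",
]


@dataclass(frozen=True)
class GeneScoreTable:
    """Gene-level fused p-values with per-gene mapped SNP counts."""

    table: pd.DataFrame  # index: gene; columns: p, n_snps

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValueError("duplicate gene in score table")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("gene p-values must lie in (0, 1]")
        if (t["n_snps"] < 1).any():
            raise ValueError("every listed gene must have >= 1 mapped SNP")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class ModuleScore:
    """Chi-square fusion score of a module's gene-level p-values."""

    module_tag: str
    statistic: float
    k: int  # scored module genes (degrees of freedom)
    p_analytic: float
    p_empirical: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.p_analytic <= 1:
            raise ValueError("analytic p must lie in (0, 1]")
        if self.p_empirical is not None:
            lower = 1.0 / (self.n_permutations + 1)
            if not lower - 1e-12 <= self.p_empirical <= 1:
                raise ValueError("empirical p outside [1/(B+1), 1]")


def map_snps_to_genes(
    gwas: GwasSummary, coords: GeneCoordinates, window_bp: int = 50_000
) -> dict[str, list[float]]:
    """Assign each SNP to the closest gene whose window contains it.

    A SNP at 0-based position x is a candidate for gene g when
    start - window <= x < end + window.  Among candidates the gene with the
    smallest distance to the gene body wins (distance 0 inside the body);
    distance ties go to the gene with the smaller start, then the
    lexicographically smaller symbol.  SNPs outside every window are left
    unassigned and counted in the log.  Raises when the two files share no
    chromosome labels.
    """
    gwas_chroms = set(gwas.table["chrom"])
    coord_chroms = set(coords.table["chrom"])
    if not gwas_chroms & coord_chroms:
        raise ValueError(
            f"no shared chromosome labels: GWAS has {sorted(gwas_chroms)}, "
            f"coordinates have {sorted(coord_chroms)}"
        )
    by_chrom = {chrom: block for chrom, block in coords.table.groupby("chrom")}
    assigned: dict[str, list[float]] = {}
    n_unassigned = 0
    for chrom, snps in gwas.table.groupby("chrom"):
        block = by_chrom.get(chrom)
        if block is None:
            n_unassigned += len(snps)
            continue
        starts = block["start"].to_numpy()
        ends = block["end"].to_numpy()
        genes = block["gene"].to_numpy(dtype=object)
        pos = snps["pos0"].to_numpy()
        ps = snps["p"].to_numpy()
        for x, p in zip(pos, ps):
            in_window = (starts - window_bp <= x) & (x < ends + window_bp)
            if not in_window.any():
                n_unassigned += 1
                continue
            cand_starts = starts[in_window]
            cand_ends = ends[in_window]
            cand_genes = genes[in_window]
            dist = np.maximum(0, np.maximum(cand_starts - x, x - (cand_ends - 1)))
            order = np.lexsort((cand_genes, cand_starts, dist))
            winner = cand_genes[order[0]]
            assigned.setdefault(winner, []).append(float(p))
    if n_unassigned:
        logger.info("%d SNPs outside every gene window left unassigned", n_unassigned)
    return assigned


def gene_score(snp_ps: Sequence[float], method: str = "sidak_min") -> float:
    """Fuse one gene's SNP p-values into a gene-level p-value."""
    p = np.asarray(snp_ps, dtype=float)
    if p.size == 0:
        raise ValueError("empty SNP p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("SNP p-values must lie in (0, 1]")
    if method == "sidak_min":
        out = 1.0 - (1.0 - p.min()) ** p.size
    elif method == "sum_chi2":
        t = stats.chi2.isf(p, df=1).sum()
        out = stats.chi2.sf(t, df=p.size)
    else:
        raise ValueError(f"unknown gene-score method {method!r}")
    return float(np.clip(out, np.finfo(float).tiny, 1.0))


def gene_score_table(
    gwas: GwasSummary,
    coords: GeneCoordinates,
    window_bp: int = 50_000,
    method: str = "sidak_min",
) -> GeneScoreTable:
    """Map SNPs to genes and score every gene with mapped SNPs."""
    assigned = map_snps_to_genes(gwas, coords, window_bp)
    if not assigned:
        raise ValueError("no SNP maps to any gene")
    genes = sorted(assigned)
    table = pd.DataFrame(
        {
            "p": [gene_score(assigned[g], method) for g in genes],
            "n_snps": [len(assigned[g]) for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return GeneScoreTable(table)


def _fusion_statistic(gene_ps: np.ndarray) -> float:
    return float(stats.chi2.isf(gene_ps, df=1).sum())


def score_module_analytic(module: Module, gene_scores: GeneScoreTable) -> ModuleScore:
    """Chi-square fusion p-value of a module's gene scores.

    Module genes absent from the score table are dropped from the degrees
    of freedom (logged), not imputed.  Zero scored genes is an error,
    deliberately distinct from a p-value of 1.
    """
    scored = sorted(module.genes & set(gene_scores.genes))
    n_dropped = len(module.genes) - len(scored)
    if n_dropped:
        logger.info("%d module genes without gene scores dropped", n_dropped)
    if not scored:
        raise ValueError("no module gene has a gene score")
    ps = gene_scores.table.loc[scored, "p"].to_numpy()
    t = _fusion_statistic(ps)
    p = float(np.clip(stats.chi2.sf(t, df=len(scored)), np.finfo(float).tiny, 1.0))
    tag = module.method or "module"
    return ModuleScore(module_tag=tag, statistic=t, k=len(scored), p_analytic=p)


def score_module_empirical(
    module: Module, gene_scores: GeneScoreTable, n_permutations: int = 10_000, seed: int = 0
) -> ModuleScore:
    """Empirical module p-value from random same-size gene sets.

    Draws ``n_permutations`` gene sets of the module's scored size
    uniformly without replacement from all scored genes; empirical
    p = (#{T_null >= T_obs} + 1) / (B + 1).
    """
    analytic = score_module_analytic(module, gene_scores)
    k = analytic.k
    all_ps = gene_scores.table["p"].to_numpy()
    if len(all_ps) <= k:
        raise ValueError(
            f"background ({len(all_ps)} scored genes) must be larger than the module (k={k})"
        )
    rng = np.random.default_rng(seed)
    quantiles = stats.chi2.isf(all_ps, df=1)
    # vectorised sampling without replacement: k smallest random keys per
    # row, in chunks to bound memory
    n = len(all_ps)
    chunk = max(1, 20_000_000 // n)
    parts = []
    for start in range(0, n_permutations, chunk):
        rows = min(chunk, n_permutations - start)
        keys = rng.random((rows, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        parts.append(quantiles[idx].sum(axis=1))
    t_null = np.concatenate(parts)
    p_emp = (np.count_nonzero(t_null >= analytic.statistic) + 1) / (n_permutations + 1)
    return ModuleScore(
        module_tag=analytic.module_tag,
        statistic=analytic.statistic,
        k=k,
        p_analytic=analytic.p_analytic,
        p_empirical=float(p_emp),
        n_permutations=n_permutations,
        seed=seed,
    )
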