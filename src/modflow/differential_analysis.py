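"""Per-gene case/control differential statistics and seed-gene selection.

The differential model is a per-gene equal-variance two-sample t-test,
i.e. the ordinary linear model with a group indicator.  This deliberately
omits empirical-Bayes variance shrinkage (the moderated t of limma-style
pipelines): point estimates are identical and the stage stays
self-contained.  Genes with zero pooled variance get p = 1 and t = 0 with
a logged warning, never NaN.

Seed genes are the top ``fraction`` (default 5%) of genes by ascending
p-value among genes present in the interaction network; the restriction to
network genes happens *before* counting, since seeds feed network methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from modflow.io_formats import GeneNetwork, OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialTable",
    "SeedSet",
    "differential_table",
    "benjamini_hochberg",
    "select_seed_genes",
    "aggregate_probes",
]


@dataclass(frozen=True)
class DifferentialTable:
    """Per-gene differential statistics.

    Columns: ``effect`` (case-minus-control mean difference), ``t``,
    two-sided ``p``, Benjamini–Hochberg ``p_adj`` and ascending-p ``rank``
    (a permutation of 1..n).
    """

    table: pd.DataFrame  # index: gene; columns: effect, t, p, p_adj, rank

    def __post_init__(self) -> None:
        t = self.table
        required = ["effect", "t", "p", "p_adj", "rank"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if (t["p_adj"] + 1e-12 < t["p"]).any():
            raise ValueError("adjusted p must be >= raw p")
        if sorted(t["rank"]) != list(range(1, len(t) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class SeedSet:
    """Seed genes for network module detection."""

    genes: frozenset[str]
    fraction: float
    source: str = ""


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min over j >= i of min(1, p_(j) * m / j) on the sorted
    scale, mapped back to the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def _two_group_stats(
    values: np.ndarray, case_idx: np.ndarray, control_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised equal-variance two-sample t-test over rows."""
    x = values[:, case_idx]
    y = values[:, control_idx]
    n1, n2 = x.shape[1], y.shape[1]
    mean_diff = x.mean(axis=1) - y.mean(axis=1)
    ss = x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    pooled = ss / df
    se = np.sqrt(pooled * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean_diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.t.sf(np.abs(t), df)
    zero_var = se == 0
    if zero_var.any():
        logger.warning("%d genes with zero pooled variance: p set to 1", int(zero_var.sum()))
        p = np.where(zero_var, 1.0, p)
        t = np.where(zero_var, 0.0, t)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return mean_diff, t, p


def differential_table(matrix: OmicsMatrix) -> DifferentialTable:
    """Per-gene case/control differential table with BH adjustment.

    Requires at least two samples per group.
    """
    cases = matrix.case_samples
    controls = matrix.control_samples
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(cases)} cases / {len(controls)} controls"
        )
    cols = list(matrix.values.columns)
    case_idx = np.array([cols.index(s) for s in cases])
    control_idx = np.array([cols.index(s) for s in controls])
    effect, t, p = _two_group_stats(matrix.values.to_numpy(float), case_idx, control_idx)
    p_adj = benjamini_hochberg(p)
    # stable tie-break on gene symbol so ranks are reproducible
    order = np.lexsort((np.asarray(matrix.features, dtype=object), p))
    rank = np.empty(len(p), dtype=int)
    rank[order] = np.arange(1, len(p) + 1)
    df = pd.DataFrame(
        {"effect": effect, "t": t, "p": p, "p_adj": p_adj, "rank": rank},
        index=matrix.features.copy(),
    )
    return DifferentialTable(df)


def select_seed_genes(
    table: DifferentialTable,
    network: GeneNetwork | Iterable[str],
    fraction: float = 0.05,
) -> SeedSet:
    """Top ``ceil(fraction * n)`` genes by p among table genes in the network.

    Ties at the boundary break by larger \\|t\\|, then lexicographically
    smaller gene symbol.  ``network`` may be a :class:`GeneNetwork` or any
    iterable of gene symbols serving as the universe.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    universe = network.nodes if isinstance(network, GeneNetwork) else frozenset(network)
    sub = table.table.loc[table.table.index.isin(universe)]
    if sub.empty:
        raise ValueError("no table gene is present in the network")
    k = math.ceil(fraction * len(sub))
    # sort by (p asc, |t| desc, symbol asc)
    sub = sub.assign(_abs_t=sub["t"].abs(), _gene=sub.index)
    ordered = sub.sort_values(by=["p", "_abs_t", "_gene"], ascending=[True, False, True])
    chosen = frozenset(ordered.index[:k])
    return SeedSet(genes=chosen, fraction=fraction)


def aggregate_probes(
    probe_table: DifferentialTable, probe_gene_map: Mapping[str, str]
) -> DifferentialTable:
    """Collapse a probe-level table to gene level.

    Gene p = 1 - (1 - min probe p)^K (Šidák over the gene's K probes);
    effect and t come from the minimum-p probe; BH is re-applied at gene
    level.  Probes absent from the map are dropped with a logged count.
    """
    t = probe_table.table
    mapped = t.loc[t.index.isin(probe_gene_map)]
    n_dropped = len(t) - len(mapped)
    if n_dropped:
        logger.info("dropping %d unmapped probes", n_dropped)
    if mapped.empty:
        raise ValueError("no probe maps to a gene")
    genes = mapped.index.map(probe_gene_map)
    grouped = mapped.assign(gene=genes)
    records = []
    for gene, block in grouped.groupby("gene", sort=True):
        k = len(block)
        best = block.loc[block["p"].idxmin()]
        gene_p = 1.0 - (1.0 - best["p"]) ** k
        gene_p = float(np.clip(gene_p, np.finfo(float).tiny, 1.0))
        records.append({"gene": gene, "effect": best["effect"], "t": best["t"], "p": gene_p})
    out = pd.DataFrame(records).set_index("gene")
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    order = np.lexsort((np.asarray(out.index, dtype=object), out["p"].to_numpy()))
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return DifferentialTable(out[["effect", "t", "p", "p_adj", "rank"]])
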