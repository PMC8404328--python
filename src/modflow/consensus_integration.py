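"""Consensus construction, top-module selection, and multi-omic integration.

The integrative workflow mirrors the benchmark's winning recipe: per
dataset, compute differential statistics and detect a module; score every
module for GWAS enrichment; per omic, keep the top-m significant modules;
build consensus modules (gene kept when present in >= x of the inputs) for
x = 1..m and keep the consensus with the best GWAS enrichment (ties prefer
the stricter threshold, i.e. the smaller higher-confidence module); finally
intersect the two per-omic consensus winners into the multi-omic module and
score it.

Consensus thresholds can also be pinned (``consensus_mode="fixed:3"``)
instead of swept, reproducing a fixed x-of-n rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

from modflow.differential_analysis import differential_table, select_seed_genes
from modflow.gwas_scoring import (
    GeneScoreTable,
    ModuleScore,
    gene_score_table,
    score_module_analytic,
)
from modflow.io_formats import (
    GeneCoordinates,
    GeneNetwork,
    GwasSummary,
    Module,
    OmicsMatrix,
)
from modflow.module_detection import (
    detect_clique_sum,
    detect_coexpression,
    detect_diamond,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WorkflowSettings",
    "IntegrationReport",
    "consensus_module",
    "select_top_modules",
    "intersect_modules",
    "run_multiomic_workflow",
]


def consensus_module(modules: Sequence[Module], min_count: int) -> Module:
    """Genes appearing in at least ``min_count`` of the input modules."""
    if not modules:
        raise ValueError("empty module list")
    if not 1 <= min_count <= len(modules):
        raise ValueError(f"min_count must lie in [1, {len(modules)}], got {min_count}")
    counts: dict[str, int] = {}
    for m in modules:
        for gene in m.genes:
            counts[gene] = counts.get(gene, 0) + 1
    genes = frozenset(g for g, c in counts.items() if c >= min_count)
    return Module(
        genes,
        method=f"consensus_{min_count}_of_{len(modules)}",
        omic=modules[0].omic if len({m.omic for m in modules}) == 1 else "",
    )


def select_top_modules(
    scored: Sequence[tuple[Module, ModuleScore]], m: int = 4, alpha: float = 0.05
) -> list[tuple[Module, ModuleScore]]:
    """Keep significant modules (p < alpha), sorted by ascending p.

    Ties break by smaller module size, then dataset tag.  Returns at most
    ``m`` entries and may return fewer (or none).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    significant = [(mod, sc) for mod, sc in scored if sc.p_analytic < alpha]
    significant.sort(key=lambda pair: (pair[1].p_analytic, len(pair[0]), pair[0].dataset))
    return significant[:m]


def intersect_modules(a: Module, b: Module) -> Module:
    """Set intersection; provenance concatenates the parents'."""
    return Module(
        a.genes & b.genes,
        method=" ∩ ".join(filter(None, [a.method, b.method])) or "intersection",
        dataset=" ∩ ".join(filter(None, [a.dataset, b.dataset])),
        omic=" ∩ ".join(filter(None, [a.omic, b.omic])) or "multi-omic",
    )


@dataclass(frozen=True)
class WorkflowSettings:
    """Tunables of the integrative workflow."""

    detector: str = "clique_sum"  # clique_sum | diamond | coexpression
    seed_fraction: float = 0.05
    alpha: float = 0.05
    m_top: int = 4
    consensus_mode: str = "sweep"  # "sweep" or "fixed:<x>"
    min_clique_size: int = 3
    clique_alpha: float = 0.01
    diamond_iterations: int = 200
    gene_score_method: str = "sidak_min"
    window_bp: int = 50_000


@dataclass
class IntegrationReport:
    """Record of every stage of one multi-omic integration run."""

    stages: list[dict] = field(default_factory=list)
    consensus: dict = field(default_factory=dict)  # omic -> {min_count, size, p}
    consensus_modules: dict = field(default_factory=dict)  # omic -> Module
    final_module: Module | None = None
    final_score: ModuleScore | None = None
    no_integration_reason: str | None = None

    @property
    def integrated(self) -> bool:
        return self.final_module is not None

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "consensus": self.consensus,
            "final_module": sorted(self.final_module.genes) if self.final_module else None,
            "final_p": self.final_score.p_analytic if self.final_score else None,
            "no_integration_reason": self.no_integration_reason,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _detect(
    settings: WorkflowSettings,
    network: GeneNetwork,
    matrix: OmicsMatrix,
    diff,
) -> Module:
    if settings.detector == "clique_sum":
        module, _ = detect_clique_sum(
            network,
            diff,
            seed_fraction=settings.seed_fraction,
            min_clique_size=settings.min_clique_size,
            clique_alpha=settings.clique_alpha,
        )
        return module
    if settings.detector == "diamond":
        seeds = select_seed_genes(diff, network, settings.seed_fraction).genes
        return detect_diamond(network, seeds, settings.diamond_iterations)
    if settings.detector == "coexpression":
        return detect_coexpression(matrix, diff, seed_fraction=settings.seed_fraction)
    raise ValueError(f"unknown detector {settings.detector!r}")


def _best_consensus(
    modules: list[Module],
    gene_scores: GeneScoreTable,
    settings: WorkflowSettings,
) -> tuple[Module, ModuleScore, int] | None:
    """Pick the consensus threshold: GWAS-p-minimising sweep or fixed x."""
    if settings.consensus_mode.startswith("fixed:"):
        x = int(settings.consensus_mode.split(":", 1)[1])
        candidates = [min(x, len(modules))]
    elif settings.consensus_mode == "sweep":
        candidates = list(range(1, len(modules) + 1))
    else:
        raise ValueError(f"unknown consensus mode {settings.consensus_mode!r}")
    best: tuple[Module, ModuleScore, int] | None = None
    for x in candidates:
        cons = consensus_module(modules, x)
        if not cons.genes or not (cons.genes & set(gene_scores.genes)):
            continue
        score = score_module_analytic(cons, gene_scores)
        # ties prefer the stricter (larger) threshold -> smaller module
        if best is None or (score.p_analytic, -x) < (best[1].p_analytic, -best[2]):
            best = (cons, score, x)
    return best


def run_multiomic_workflow(
    datasets_per_omic: dict[str, Sequence[OmicsMatrix]],
    network: GeneNetwork,
    gwas: GwasSummary,
    coords: GeneCoordinates,
    settings: WorkflowSettings | None = None,
) -> IntegrationReport:
    """Run the full integrative workflow over two (or more) omic groups.

    Deterministic: every stage is a pure function of its inputs.  When an
    omic yields no significant module the report flags "no integration
    possible" instead of raising.
    """
    settings = settings or WorkflowSettings()
    if not datasets_per_omic:
        raise ValueError("need at least one omic group")
    for omic, datasets in datasets_per_omic.items():
        if not datasets:
            raise ValueError(f"omic {omic!r} has no datasets")
    report = IntegrationReport()
    gene_scores = gene_score_table(
        gwas, coords, window_bp=settings.window_bp, method=settings.gene_score_method
    )
    winners: dict[str, Module] = {}
    for omic in sorted(datasets_per_omic):
        scored: list[tuple[Module, ModuleScore]] = []
        for i, matrix in enumerate(datasets_per_omic[omic]):
            tag = f"{omic}_{i + 1}"
            diff = differential_table(matrix)
            module = _detect(settings, network, matrix, diff)
            module = module.with_provenance(dataset=tag, omic=omic)
            entry = {"omic": omic, "dataset": tag, "method": module.method,
                     "size": len(module)}
            if module.genes & set(gene_scores.genes):
                score = score_module_analytic(module, gene_scores)
                entry["gwas_p"] = score.p_analytic
                scored.append((module, score))
            else:
                entry["gwas_p"] = None
            report.stages.append(entry)
        top = select_top_modules(scored, m=settings.m_top, alpha=settings.alpha)
        if not top:
            report.no_integration_reason = f"no significant module for omic {omic!r}"
            logger.warning("no integration possible: %s", report.no_integration_reason)
            continue
        best = _best_consensus([mod for mod, _ in top], gene_scores, settings)
        if best is None:
            report.no_integration_reason = f"no scorable consensus for omic {omic!r}"
            logger.warning("no integration possible: %s", report.no_integration_reason)
            continue
        cons, score, x = best
        cons = cons.with_provenance(omic=omic)
        winners[omic] = cons
        report.consensus[omic] = {"min_count": x, "n_inputs": len(top),
                                  "size": len(cons), "gwas_p": score.p_analytic}
        report.consensus_modules[omic] = cons
    if report.no_integration_reason is not None or len(winners) < 2:
        if report.no_integration_reason is None:
            report.no_integration_reason = "fewer than two omics produced a consensus module"
        return report
    omics = sorted(winners)
    final = winners[omics[0]]
    for omic in omics[1:]:
        final = intersect_modules(final, winners[omic])
    report.final_module = final
    if final.genes & set(gene_scores.genes):
        report.final_score = score_module_analytic(final, gene_scores)
    else:
        report.no_integration_reason = "final intersection has no scorable genes"
    return report
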