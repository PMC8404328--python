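"""Synthetic multi-omic study generator with a planted ground-truth module.

Emulates every input the workflow consumes, so all downstream stages are
testable without downloads:

* a random interaction network (Erdős–Rényi background) with a planted
  dense module — by default a dense random subgraph rather than a perfect
  clique, so clique-based detection recovers it only partially, mirroring
  realistic behaviour; a ``perfect_clique`` toggle exists for
  exact-recovery tests;
* case/control expression matrices: gene values ~ Normal(0, noise_sd),
  cases shifted by ``effect_size`` standard deviations on flagged genes;
* case/control methylation beta matrices: per-gene baseline beta with
  Gaussian noise and the case shift applied on the log-odds scale, then
  mapped back through the logistic function so values stay in [0, 1];
* non-overlapping gene coordinates on synthetic chromosomes;
* GWAS summary statistics: each gene receives K ~ Uniform{min..max} SNPs
  inside its window; null SNP p-values are Uniform(0, 1); SNPs of signal
  genes draw a noncentral chi-square(1, λ) statistic and report the central
  chi-square(1) upper-tail p, the standard association-signal model;
* risk-factor gene sets overlapping the planted module at a controlled
  fraction.

Determinism: one master seed fixes every component through
``numpy.random.SeedSequence.spawn`` with a documented, fixed spawn order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from modflow.io_formats import (
    GeneCoordinates,
    GeneNetwork,
    GeneSetCollection,
    GwasSummary,
    OmicsMatrix,
)

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "generate_network",
    "generate_omics",
    "generate_gene_coords",
    "generate_gwas",
    "generate_risk_sets",
    "simulate_study",
    "SyntheticStudy",
]


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic multi-omic benchmark.

    Defaults describe the reference study: a 1000-gene network with a
    planted 50-gene dense module, 40 cases vs 40 controls per dataset, a
    1.5-SD differential effect on module genes, and GWAS SNPs at module
    genes inflated with noncentrality λ = 15.
    """

    n_genes: int = 1000
    background_edge_prob: float = 0.02
    module_size: int = 50
    module_edge_prob: float = 0.6
    perfect_clique: bool = False
    n_case: int = 40
    n_control: int = 40
    effect_size: float = 1.5
    noise_sd: float = 1.0
    snps_per_gene_range: tuple[int, int] = (1, 10)
    gwas_noncentrality: float = 15.0
    signal_gene_fraction: float = 1.0
    n_risk_sets: int = 5
    risk_set_size: int = 100
    risk_overlap_fraction: float = 0.3
    n_datasets_per_omic: int = 4
    gene_length_bp: int = 10_000
    gene_spacing_bp: int = 120_000
    n_chromosomes: int = 22
    network_min_score: int = 700

    def __post_init__(self) -> None:
        if not 0 < self.module_size < self.n_genes:
            raise ValueError("module_size must satisfy 0 < module_size < n_genes")
        for name in ("background_edge_prob", "module_edge_prob", "signal_gene_fraction",
                     "risk_overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.module_edge_prob < self.background_edge_prob:
            raise ValueError("module_edge_prob must be >= background_edge_prob")
        if self.gwas_noncentrality < 0:
            raise ValueError("gwas_noncentrality must be >= 0")
        lo, hi = self.snps_per_gene_range
        if not 1 <= lo <= hi:
            raise ValueError("snps_per_gene_range must satisfy 1 <= min <= max")
        if self.risk_set_size > self.n_genes:
            raise ValueError("risk_set_size must not exceed n_genes")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted by the simulator; oracle for recovery tests."""

    module: frozenset[str]
    expression_flags: frozenset[str]
    methylation_flags: frozenset[str]
    gwas_flags: frozenset[str]
    risk_membership: dict[str, frozenset[str]] = field(default_factory=dict)
    component_seeds: dict[str, int] = field(default_factory=dict)

    def flags(self, kind: str) -> frozenset[str]:
        if kind == "expression":
            return self.expression_flags
        if kind == "methylation-beta":
            return self.methylation_flags
        if kind == "gwas":
            return self.gwas_flags
        raise KeyError(kind)


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit component seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _flag_subset(rng: np.random.Generator, module: list[str], fraction: float) -> frozenset[str]:
    k = int(round(fraction * len(module)))
    return frozenset(rng.choice(module, size=k, replace=False)) if k else frozenset()


def generate_network(config: SimulationConfig, seed: int) -> tuple[GeneNetwork, PlantedTruth]:
    """Random background network with a planted dense module.

    Background pairs connect independently with ``background_edge_prob``;
    pairs inside the planted module with ``module_edge_prob`` (probability
    1 when ``perfect_clique``).  Edge confidence scores are sampled
    uniformly in (min_score, 1000], i.e. above the working threshold, so
    the generated file survives its own read filter.
    """
    seeds = _spawn_seeds(seed, 5)
    rng = np.random.default_rng(seeds[0])
    genes = _gene_names(config.n_genes)
    module = sorted(rng.choice(genes, size=config.module_size, replace=False))
    module_set = frozenset(module)
    g = nx.Graph()
    g.add_nodes_from(genes)
    p_mod = 1.0 if config.perfect_clique else config.module_edge_prob
    lo_score = config.network_min_score + 1
    iu, iv = np.triu_indices(config.n_genes, k=1)
    in_module = np.isin(np.arange(config.n_genes), [genes.index(m) for m in module])
    pair_prob = np.where(
        in_module[iu] & in_module[iv], p_mod, config.background_edge_prob
    )
    keep = rng.random(pair_prob.size) < pair_prob
    scores = rng.integers(lo_score, 1001, size=int(keep.sum()))
    gene_arr = np.asarray(genes, dtype=object)
    for u, v, s in zip(gene_arr[iu[keep]], gene_arr[iv[keep]], scores):
        g.add_edge(u, v, score=int(s))
    # drop unconnected background genes; planted-module genes always stay so
    # the truth module is a subset of the network nodes
    g.remove_nodes_from([n for n in nx.isolates(g) if n not in module_set])
    flag_rngs = [np.random.default_rng(s) for s in seeds[1:4]]
    truth = PlantedTruth(
        module=module_set,
        expression_flags=_flag_subset(flag_rngs[0], module, config.signal_gene_fraction),
        methylation_flags=_flag_subset(flag_rngs[1], module, config.signal_gene_fraction),
        gwas_flags=_flag_subset(flag_rngs[2], module, config.signal_gene_fraction),
        component_seeds={"network": seeds[0]},
    )
    return GeneNetwork(g), truth


def generate_omics(
    truth: PlantedTruth, config: SimulationConfig, kind: str, seed: int,
    dataset: str = "sim",
) -> OmicsMatrix:
    """One case/control omics dataset with differential signal on flagged genes."""
    if config.n_case < 2 or config.n_control < 2:
        raise ValueError("need >= 2 cases and >= 2 controls")
    rng = np.random.default_rng(seed)
    genes = _gene_names(config.n_genes)
    n_samples = config.n_case + config.n_control
    flags = truth.flags(kind)
    flag_mask = np.array([g in flags for g in genes])
    shift = np.zeros((config.n_genes, n_samples))
    shift[flag_mask, : config.n_case] = config.effect_size * config.noise_sd
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    if kind == "expression":
        values = noise + shift
    elif kind == "methylation-beta":
        baseline = _logit(rng.uniform(0.2, 0.8, size=config.n_genes))[:, None]
        values = _expit(baseline + noise + shift)
    else:
        raise ValueError(f"unknown omics kind {kind!r}")
    samples = [f"{dataset}_case{i}" for i in range(config.n_case)] + [
        f"{dataset}_ctrl{i}" for i in range(config.n_control)
    ]
    labels = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control, index=samples
    )
    df = pd.DataFrame(values, index=pd.Index(genes, name="feature"), columns=samples)
    return OmicsMatrix(values=df, labels=labels, kind=kind)


def generate_gene_coords(
    network: GeneNetwork | list[str], config: SimulationConfig, seed: int
) -> GeneCoordinates:
    """Non-overlapping gene intervals laid out across synthetic chromosomes.

    Genes are placed in a deterministic round-robin over ``n_chromosomes``
    chromosomes with fixed length and spacing; a small random jitter
    (bounded by the spacing margin) keeps layouts seed-dependent without
    ever producing overlap.
    """
    genes = sorted(network.nodes) if isinstance(network, GeneNetwork) else sorted(network)
    if not genes:
        raise ValueError("network has no genes")
    rng = np.random.default_rng(seed)
    margin = max(config.gene_spacing_bp - config.gene_length_bp - 1, 0)
    records = []
    per_chrom = -(-len(genes) // config.n_chromosomes)  # ceil
    for i, gene in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        jitter = int(rng.integers(0, margin // 4 + 1))
        start = slot * config.gene_spacing_bp + jitter
        records.append(
            {"gene": gene, "chrom": chrom, "start": start, "end": start + config.gene_length_bp}
        )
    df = pd.DataFrame(records).sort_values(["chrom", "start"], kind="stable")
    return GeneCoordinates(df.reset_index(drop=True)[["gene", "chrom", "start", "end"]])


def generate_gwas(
    truth: PlantedTruth, coords: GeneCoordinates, config: SimulationConfig, seed: int
) -> GwasSummary:
    """GWAS summary statistics with inflated association at module-gene SNPs.

    Null SNPs draw p ~ Uniform(0, 1).  SNPs of GWAS-flagged genes draw a
    noncentral chi-square(1, λ) statistic and report the central
    chi-square(1) upper-tail probability.
    """
    if config.gwas_noncentrality < 0:
        raise ValueError("noncentrality must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = config.snps_per_gene_range
    records = []
    snp_i = 0
    for row in coords.table.itertuples(index=False):
        k = int(rng.integers(lo, hi + 1))
        positions = np.sort(rng.integers(row.start, row.end, size=k))
        is_signal = row.gene in truth.gwas_flags
        if is_signal and config.gwas_noncentrality > 0:
            chi = stats.ncx2.rvs(
                df=1, nc=config.gwas_noncentrality, size=k, random_state=rng
            )
            ps = stats.chi2.sf(chi, df=1)
        else:
            ps = rng.uniform(0.0, 1.0, size=k)
        ps = np.clip(ps, np.finfo(float).tiny, 1.0)
        for pos, p in zip(positions, ps):
            records.append(
                {"snp": f"rs{snp_i}", "chrom": row.chrom, "pos0": int(pos), "p": float(p)}
            )
            snp_i += 1
    return GwasSummary(pd.DataFrame(records, columns=["snp", "chrom", "pos0", "p"]))


def generate_risk_sets(
    truth: PlantedTruth, config: SimulationConfig, seed: int
) -> GeneSetCollection:
    """Risk-factor gene sets overlapping the planted module at a set fraction.

    Each set draws round(size × overlap_fraction) genes from the truth
    module (capped at the module size) and fills the remainder uniformly
    from non-module genes, without replacement.
    """
    if config.risk_set_size > config.n_genes:
        raise ValueError("risk set size exceeds number of genes")
    rng = np.random.default_rng(seed)
    genes = _gene_names(config.n_genes)
    module = sorted(truth.module)
    background = sorted(set(genes) - truth.module)
    n_from_module = min(
        int(round(config.risk_set_size * config.risk_overlap_fraction)), len(module)
    )
    sets = []
    for i in range(config.n_risk_sets):
        from_module = rng.choice(module, size=n_from_module, replace=False)
        from_background = rng.choice(
            background, size=config.risk_set_size - n_from_module, replace=False
        )
        members = frozenset(from_module) | frozenset(from_background)
        sets.append((f"risk_factor_{i + 1}", "synthetic risk-factor DMG set", members))
    return GeneSetCollection(tuple(sets))


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete synthetic multi-omic study (all workflow inputs + truth)."""

    network: GeneNetwork
    truth: PlantedTruth
    coords: GeneCoordinates
    gwas: GwasSummary
    expression: tuple[OmicsMatrix, ...]
    methylation: tuple[OmicsMatrix, ...]
    risk_sets: GeneSetCollection
    config: SimulationConfig
    master_seed: int


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate the full reference study from one master seed.

    Spawn order (fixed): network+flags, coordinates, GWAS, risk sets, then
    ``n_datasets_per_omic`` expression and methylation datasets.
    """
    config = config or SimulationConfig()
    n_components = 4 + 2 * config.n_datasets_per_omic
    seeds = _spawn_seeds(seed, n_components)
    network, truth = generate_network(config, seeds[0])
    coords = generate_gene_coords(_gene_names(config.n_genes), config, seeds[1])
    gwas = generate_gwas(truth, coords, config, seeds[2])
    risk_sets = generate_risk_sets(truth, config, seeds[3])
    expr = tuple(
        generate_omics(truth, config, "expression", seeds[4 + i], dataset=f"expr{i + 1}")
        for i in range(config.n_datasets_per_omic)
    )
    meth = tuple(
        generate_omics(
            truth, config, "methylation-beta",
            seeds[4 + config.n_datasets_per_omic + i], dataset=f"meth{i + 1}",
        )
        for i in range(config.n_datasets_per_omic)
    )
    return SyntheticStudy(
        network=network,
        truth=truth,
        coords=coords,
        gwas=gwas,
        expression=expr,
        methylation=meth,
        risk_sets=risk_sets,
        config=config,
        master_seed=seed,
    )
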