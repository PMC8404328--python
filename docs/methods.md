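# Methods

## Model and workflow

`modflow` treats disease-module detection as a three-stage inference
problem on an undirected, confidence-weighted gene interaction network
G = (V, E, w), w ∈ [0, 1000]:

1. **Differential evidence.** Each omics dataset is a feature × sample
   matrix with case/control labels. Per gene we fit the two-group linear
   model y = β₀ + β₁·case + ε with homoscedastic ε, equivalent to the
   equal-variance two-sample *t* test; two-sided p-values are
   BH-adjusted. Seed genes are the ⌈f·n⌉ network genes with the smallest
   p (f = 0.05 by default, the "dynamic 5 % cutoff"); ties break by
   larger |t|, then lexicographic symbol, making selection deterministic
   and row-order invariant. For methylation arrays a probe-level table
   collapses to genes by Šidák min-p over each gene's K probes,
   p_gene = 1 − (1 − min p)^K, carrying effect and t from the min-p probe;
   BH is re-applied at gene level. The Šidák rule is our choice; any
   aggregation that is a calibrated p-value under the null would do.

2. **Module detection.** Three exemplars, one per algorithm class:
   - *Clique-based* ("Clique SuM" reconstruction): all maximal cliques of
     size ≥ 3 (Bron–Kerbosch, networkx `find_cliques`); each clique is
     tested for seed enrichment with the one-sided hypergeometric tail
     P(X ≥ s) for s observed seeds in a clique of size c drawn from N
     network genes containing S seeds; BH across cliques; the module is
     the union of cliques with adjusted p < 0.01. The published method's
     internals are not public in detail; this reconstruction keeps its
     two essential commitments — fully connected building blocks and
     differential-seed enrichment.
   - *Seed-based* (DIAMOnD): greedily add the candidate v minimising the
     hypergeometric tail P(X ≥ k_v) of its k_v links into the current
     member set (universe = all nodes, draws = deg v). No seed weighting
     (α = 1). Ties break by more links, then lexicographic symbol — the
     original leaves ties unspecified, so we fix them for determinism.
   - *Co-expression-based*: signed adjacency a_ij = ((1 + r_ij)/2)^β with
     β = 6, dissimilarity 1 − a, average-linkage hierarchical clustering,
     a sweep of 20 evenly spaced cut heights keeping the cut with the
     most clusters of size ≥ 10, and among those clusters the one most
     enriched for seeds (hypergeometric). This deliberately replaces the
     topological-overlap matrix and dynamic tree cut of full WGCNA with
     plainer machinery; it is an exemplar of the class, not a WGCNA
     reimplementation.

3. **Genomic-concordance scoring** (Pascal-style). SNP p-values map to
   the closest gene whose window [start − 50 kb, end + 50 kb) contains
   the SNP (distance 0 inside the body; ties → smaller start, then
   symbol). Gene score: Šidák min-p over the gene's K SNPs (default,
   the "max" statistic) or the chi-square sum variant
   T = Σ Q_{χ²(1)}(1 − p_i), p = P(χ²(K) ≥ T); both coincide at K = 1.
   Module score: T = Σ_g Q_{χ²(1)}(1 − p_g) over the k scored module
   genes, p = P(χ²(k) ≥ T). Genes without scores are dropped from k, not
   imputed. An optional empirical p draws B same-size gene sets without
   replacement, p = (#{T_null ≥ T} + 1)/(B + 1). All fusion assumes
   independent SNPs and genes: the simulator generates no linkage
   disequilibrium, and LD-aware decorrelation against a reference panel
   is explicitly out of scope — on real GWAS these scores would be
   anti-conservative near strong LD.

**Integration.** Per omic: score every detected module, keep modules with
p < 0.05 sorted by p (ties → smaller module, then dataset tag), truncate
to m = 4. Consensus x/n = genes in ≥ x of the n kept modules; x is chosen
by minimising the consensus module's GWAS p over x = 1..n, ties to the
larger x (stricter, higher-confidence module). A fixed x can be pinned via
`consensus_mode="fixed:x"`, reproducing an a-priori x-of-n rule. The final
multi-omic module is the intersection of the per-omic winners and is
scored the same way. An omic with no significant module flags
"no integration possible" rather than erroring.

## Synthetic data: what it emulates and what it does not

The generator plants a module M of 50 genes in a 1000-gene network:
background pairs connect with probability 0.02, within-module pairs with
0.6 (a dense random subgraph, not a clique, so clique-based detection
recovers the module through overlapping cliques rather than trivially; a
`perfect_clique` toggle exists for exact-recovery tests). Edge scores are
uniform above the working threshold (700), so written networks survive
their own read filter. Defaults per dataset: 40 cases vs 40 controls,
effect 1.5 SD on flagged genes (all of M by default), unit noise;
methylation applies the shift on the log-odds of a Uniform(0.2, 0.8)
baseline beta and maps back through the logistic, keeping values in
[0, 1]. GWAS: 1–10 SNPs per gene inside the gene body; null SNPs draw
p ~ U(0, 1); SNPs of flagged genes draw a noncentral χ²(1, λ = 15)
statistic and report the central χ²(1) tail. Risk-factor sets of 100
genes overlap M at a fixed fraction (0.3), remainder from non-module
genes. Four datasets per omic mirror the m = 4 top-module selection. One
master seed fixes everything through `SeedSequence.spawn` in a fixed
order.

Not emulated: linkage disequilibrium and realistic allele frequencies,
probe-level array structure, batch effects, cell-type composition,
covariates, and between-dataset heterogeneity beyond independent noise.
Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under independence — not robustness to the
technical structure of real cohorts.

## Numerical choices

- p-values are clipped to [tiny, 1] before logs and chi-square quantiles;
  a GWAS input p of exactly 0 is rejected at read time (it breaks the
  chi-square transform) — pre-floor upstream if needed.
- Zero pooled variance ⇒ p = 1, t = 0, logged; never NaN.
- The network score filter is strict (score > threshold) at both 700 and
  900; reversed duplicate edges keep the maximum score.
- BED intervals are 0-based half-open; GWAS positions are 1-based on disk
  and converted to 0-based at read time, so one convention holds
  internally.
- Permutation sampling without replacement is vectorised (k smallest of a
  row of uniform keys), chunked to bound memory.
- Empty modules are legal objects; they contribute no p-value to meta-p
  (shown as missing cells), distinct from p = 1.
- Haldane–Anscombe +0.5 enters an odds ratio only when a zero cell
  occurs, and the result is flagged.
- Binomial excess tests are one-sided upper tail including k. Spearman
  significance uses the t-approximation (exact permutation does not scale
  to n ≈ 337 and the approximation reproduces all printed values).

## Problem sizes used by the test and acceptance suites

Chosen as the package's reference conditions: the recovery study runs the
full default simulator (1000 genes, module 50, 4 datasets × 2 omics,
λ = 15) over 10 master seeds and requires median F1 ≥ 0.7 for the final
module; null-calibration suites run at 300 genes / module 30 (effect 0,
λ = 0) over 100 seeds for the detector false-module rate and 200 fresh
GWAS realizations for module-score uniformity. Module scores that share
one realized gene-score table are strongly dependent, so calibration
checks draw one random module per fresh GWAS realization (or spread draws
over ≥ 50 realizations) before applying binomial/KS bands.

## Known limitations

- Only one exemplar per detection class; the clique scorer is a
  reconstruction, not a port, of the published clique method.
- Equal-variance t instead of an empirical-Bayes moderated t: with tens
  of samples per group the difference is small; with very few samples the
  moderated variant is strictly better.
- Gene identity is the bare case-sensitive symbol; no identifier mapping.
- The workflow interface accepts any number of omic groups but is
  designed and tested for two.
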