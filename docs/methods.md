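# Methods

This document records the model implemented by `gcna_kpca`, its
assumptions, the default parameters and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
and design decisions made where the method description leaves latitude.

## 1. Pipeline overview

Input: a gene × sample expression matrix (FPKM-like, non-negative),
tumor/normal sample labels, and optionally an annotation catalogue
(GMT), survival times, and a PPI edge list.

1. **Preprocessing** (four sequential filters)
   1. Drop genes whose maximum expression is below `min_max = 1.0` in
      every sample group. The threshold is applied per group and a gene
      is kept if *either* group clears it (a gene silenced in tumors but
      expressed in normals is differentially interesting, not noise);
      `require_both=True` switches to the stricter reading.
   2. Flag outlier samples by average-linkage hierarchical clustering
      on Euclidean distances between sample profiles: a sample is
      flagged when the height at which its leaf first merges exceeds
      mean + 2.5 sd of all leaf first-merge heights. Flagged samples
      are reported; dropping them is opt-in (`auto_drop_outliers`).
      Under a Gaussian null this flags ~1% of samples; note that
      because first-merge heights are right-skewed, roughly 20% of
      *datasets* of 20 null samples contain at least one flag, so the
      report should be reviewed rather than applied blindly.
   3. Keep genes with tumor/normal fold change ≥ 2 or ≤ 0.5
      (inclusive), computed on means with pseudocount 1e-3.
   4. Keep genes with Welch two-sample t-test p < 0.05 (scipy
      `ttest_ind(equal_var=False)`; a NaN statistic maps to p = 1).

2. **Co-expression network**: Pearson correlation for all gene pairs;
   edge iff `|r| ≥ 0.65` and `p < 0.05`, with p from the
   t-transformation `t = r√(m−2)/√(1−r²)` on m samples (df = m−2).
   Edge weight is `|r|`; the sign is kept as an attribute. A gene with
   zero variance is rejected by name. An optional Bonferroni flag
   divides alpha by the number of pairs.

3. **Community detection** (module seeding): Newman's
   leading-eigenvector modularity maximization, implemented here (not
   delegated). Each candidate community is bisected by the sign
   pattern of the dominant eigenvector of its generalized modularity
   matrix `B^(g) = B − diag(rowsums)`, where `B = A − k kᵀ/2m`; the
   split is refined by a Kernighan–Lin-style sweep (each node flipped
   exactly once per pass in best-gain order, keeping the best
   intermediate state) and accepted only if the modularity gain exceeds
   1e-12. Connected components are processed independently against the
   full graph's degrees and 2m. After recursion bottoms out, a global
   fine-tuning pass greedily relocates single vertices between
   communities while any positive modularity gain remains. Degree-0
   genes are set aside as "isolated" and are assigned to modules later
   by expression distance, not dropped. The network is treated as
   unweighted for modularity (an edge exists or not), matching the
   thresholded-network construction; `weighted=True` uses |r|
   strengths. The method is a heuristic: on small random graphs it
   attains ≥ 0.9 × the exhaustively optimal Q across a seeded battery
   (tested), but graphs exist where the optimum requires a community
   count unreachable by bisection plus single-vertex moves.

4. **Eigengene**: member rows are standardized (mean 0, sd 1 per
   gene); the eigengene is the first right-singular vector of that
   matrix, unit norm, with sign fixed so that it correlates
   non-negatively with the mean standardized profile (deterministic
   fallback to a positive leading entry if that correlation is exactly
   zero).

5. **Correlation K-means**: K and the initial centers come from step 3
   (K = number of communities of size ≥ `min_module_size = 3`; centers
   are their eigengenes). Each iteration assigns every gene to the
   center minimizing `D(g, C) = 1 − |cor(x_g, C)|` (ties to the lowest
   module id), then recomputes each center as the eigengene of its
   members; clusters falling below `min_module_size` are dissolved and
   their genes reassigned. Termination is an exact labeling fixpoint
   (no gene changes side), capped at `max_iter = 100`. If the label
   sequence revisits a previous state (oscillation), the visited state
   with the lowest module-membership error rate is returned and the
   trace marks non-convergence. At a fixpoint the final centers are by
   construction the eigengenes of the final modules, which is why the
   refined error rate (below) is typically 0.

6. **Evaluation**
   - *Error rate*: gene g in module i violates membership iff some
     j ≠ i has `|cor(x_g, ME_j)| > |cor(x_g, ME_i)|` (strict; exact
     ties are not violations). With a single module the rate is 0 by
     vacuity (warned).
   - *Biological significance*: per module,
     `Sig_i = Σ −log10(p_t)` over terms with hypergeometric
     upper-tail p < 0.05 (`hypergeom.sf(overlap−1, N, K, n)`);
     `Sig` is the mean of `Sig_i` over modules. Summing only
     significant terms is a deliberate reading: summing over the whole
     catalogue would scale with catalogue size rather than enrichment.
     The background defaults to the clustered genes.
   - *Prognostic significance*: samples are split at the median of a
     gene's expression (ties at or below the cut go to the low
     stratum; a degenerate split gives p = 1 with a warning); the
     two-sided logrank p comes from `lifelines`. `Sig_SA = Σ −log10 p`
     over the key genes, with p floored at 1e-300.
   - *AUC*: rank-sum (midrank) formulation; directional, so a gene
     down-regulated in tumors scores below 0.5.

7. **Key genes**: the module with the highest `Sig_i` (ties to the
   lowest id) is the key module. Its genes induce a PPI subgraph
   (genes absent from the PPI are excluded and logged) and are ranked
   by PageRank — authored power iteration, damping 0.85,
   column-stochastic with dangling nodes redistributed uniformly, L1
   tolerance 1e-10, max 1000 iterations (failure raises with the
   residual). PageRank is unweighted by default, matching binary
   interaction evidence; `weighted=True` uses edge scores. The top 10
   genes (score ties broken lexicographically) are reported.

## 2. Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| `min_max` (expression filter) | 1.0 | conventional FPKM floor for "expressed" |
| outlier z-cut | 2.5 | flags only extreme sample profiles (~1% per-sample null rate) |
| fold-change bounds | ≥2 or ≤0.5 | standard 2-fold DE screen, inclusive |
| t-test alpha | 0.05 | standard screen; Welch variant avoids equal-variance assumption |
| PCC threshold / alpha | 0.65 / 0.05 | strong-correlation edges; p-filter removes small-sample artifacts |
| `min_module_size` | 3 | an eigengene of <3 genes is not a meaningful summary |
| `max_iter` | 100 | fixpoint is typically reached in <5 iterations |
| PageRank damping / tol | 0.85 / 1e-10 | canonical damping; tolerance far below score gaps |
| top-k key genes | 10 | reporting convention |
| default seed | 17 | arbitrary, fixed for reproducibility |

## 3. Synthetic data generator

`SimulationSpec` defaults ("small" preset): 5 modules × 20 genes + 100
background genes; 30 tumor + 30 normal samples; within-module latent
correlation ρ = 0.8; DE effect 2.0 on the log scale applied to module
genes with direction alternating per module; hazard ratio 2.0; 30%
censoring. These conditions were fixed before any evaluation was run.

Mechanism: each module has a per-sample latent factor; a member gene's
log-expression is `√ρ·factor + √(1−ρ)·noise`, shifted by
`d·(group−0.5)` with the module's DE sign, then mapped to an FPKM-like
scale by `exp(0.5·z + log 5)`. Background genes are pure noise.
Annotations mirror each planted module (plus a couple of noise genes
per term) with decoy terms; survival is exponential with per-sample
hazard `0.1 · HR^e_s` where `e_s` is the standardized module-0
eigengene score, censored by an independent exponential calibrated to
the target rate; the PPI plants one hub per module (degree 8 within the
module) over sparse Erdős–Rényi background edges.

What it emulates: block-correlated expression with known module truth,
group-differential modules, outcome linked to one module's activity,
hub-centered interaction structure. What it does not emulate: heavy
tails and zero inflation of real RNA-seq counts, overlapping modules,
batch effects, correlated annotation terms, realistic PPI topology
(scale-free degree distributions), or covariate-dependent censoring.

## 4. Numerical and design decisions

- **Determinism**: every stochastic step is seeded; identical seeds and
  inputs give byte-identical partition files (tested). Module ids are
  renumbered by first appearance in gene order.
- **Tie-breaking**: assignment ties → lowest module id; key-module ties
  → lowest module id; PageRank score ties → lexicographic gene id;
  eigenvector entries exactly 0 in bisection → the +1 side.
- **Oscillation**: K-means under a non-metric distance with
  recomputed PCA centers is not guaranteed to descend a single
  objective; cycles are detected by hashing the label vector and
  resolved by the minimum-error-rate visited state.
- **Isolated network genes** join K-means with everyone else; they
  influence no seed center but receive a module by expression distance.
- **Zero community count** (network too sparse to seed any module of
  size ≥ 3) raises an actionable error suggesting a lower correlation
  threshold.
- **p-value floors**: −log10 aggregation floors p at 1e-300 to avoid
  infinities from underflow.
- **Sample scope**: the CLI pipeline clusters tumor samples by default
  (module discovery within the disease group); `--cluster-samples all`
  uses every sample. The library function clusters whatever matrix it
  receives.

## 5. Problem sizes exercised

Unit and acceptance tests run the full pipeline on the small preset
(200 genes × 60 samples) across 50 seeds, community detection against
exhaustive optima on graphs up to 10 nodes (all set partitions), and
statistical calibration with 1000 null survival replicates. The CLI
`--preset paper-scale` (20 modules × 150 genes + 1601 background,
367 + 49 samples) exercises a realistically sized run in under a
minute.
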