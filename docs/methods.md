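# Methods

## Model and procedure

The pipeline tests, for every gene pair, whether the pair's co-expression
differs between two conditions R and S. Within each condition the Pearson
correlation is computed across that condition's samples (time points and
replicates pooled — samples are treated as exchangeable), Fisher-transformed
(z = ½·ln((1+r)/(1−r))), and the two transforms compared with

δ = (z_R − z_S) / √(1/(n_R−3) + 1/(n_S−3)),

the classical two-sample Fisher-z statistic whose null distribution is
approximately standard normal when n > 3 in both conditions. Two-sided
normal p-values are provided for reference, but edge selection uses the
local false discovery rate computed jointly over all pairs; an edge enters
the differential network when lfdr < 0.05 (strict). The sign convention is
+1 for δ > 0, i.e. the pair is more correlated in the resistant condition.

### Local FDR estimator

lfdr(δ) = η₀·f₀(|δ|)/f(|δ|) with three fitted ingredients:

- **f**, the marginal density of |δ|: the Grenander estimator — the left
  derivative of the least concave majorant of the empirical CDF, computed
  by pool-adjacent-violators on the ECDF slopes. It is non-increasing by
  construction, which is the correct shape constraint for a folded test
  statistic, and requires no bandwidth.
- **f₀**, the null: a half-normal whose scale is fitted by truncated
  maximum likelihood on the central portion of |δ|. The truncation cutoff
  starts at the 0.75 quantile of |δ| and is then refitted as the matching
  quantile of the fitted null until the fixed point converges
  (central-matching style). The iteration matters when non-null pairs are
  plentiful: a pure quantile cutoff then sits inside the signal and
  inflates the null scale, halving power.
- **η₀**, the null proportion: the censoring estimate
  #{|δ| ≤ cutoff}/m divided by the null mass below the cutoff, capped at 1.

Raw ratios are clipped to [0, 1] and forced monotone non-increasing in |δ|
by isotonic regression, so a larger statistic can never look less
significant. A p-value input mode (Grenander on p with a uniform null,
η₀ from the density at p → 1) is available behind `lfdr_input="pvalue"`;
the δ-input mode is the default.

The estimator assumes the centre of the δ distribution is null-dominated.
Degenerate input (all values identical) is an error when the estimator is
called directly; the edge-table builder special-cases the fully degenerate
situation of identical condition matrices (all δ = 0) as "no evidence
against any null" (lfdr = 1 everywhere), which is the only sensible answer
there. Fewer than 50 statistics triggers a warning.

## Network, modules, hubs

The per-pair δ values are assembled into a symmetric matrix, scaled to
A = |δ|/max|δ| ∈ [0, 1] with zero diagonal, and converted to the standard
unsigned weighted topological overlap,

TOM_ij = (Σ_u A_iu·A_uj + A_ij) / (min(k_i, k_j) + 1 − A_ij), TOM_ii = 1,

which credits shared neighbourhoods and stabilises clustering of noisy
adjacencies. Modules come from average-linkage hierarchical clustering of
1 − TOM with a dynamic cut: the cut height is the 0.99 quantile of the
merge heights, capped at 1 − 10⁻³ so branches that only join at maximal
dissimilarity (zero overlap) are never merged — this is what makes an
identity-like TOM yield no modules rather than one giant one. Branches
below `min_module_size` (default 20) merge into the retained module with
the highest mean TOM when that exceeds the global mean off-diagonal
overlap, otherwise they stay unassigned (label 0). Labels are ordered by
decreasing module size (the size-rank colour convention: module 1 =
"turquoise", 2 = "blue", ...); ties break on the lowest gene index, so the
assignment is deterministic. A fixed-k cut is available via
`method="fixed_k"`.

Clustering runs on ALL analysed genes by default (TOM is defined on the
full scaled matrix); the reported node count refers to genes carrying at
least one significant edge, matching how differential-network sizes are
conventionally quoted. `cluster_scope="significant"` restricts clustering
to those nodes instead. In the pipeline, a detected branch containing no
significant intramodular edge is demoted to label 0: a module of a
*differential* network must carry differential signal, and this is what
lets a no-signal run report zero modules instead of one noise blob.

Hubs are ranked by signed connectivity kWithin(u) = conn⁺(u) − conn⁻(u)
over u's significant intramodular edges, where conn⁺ sums positive edge
weights and conn⁻ is the absolute sum of negative ones. Default weights
are the signed scaled δ (sign(δ)·|δ|/max|δ| with the max taken over the
full edge table, so weights match the network adjacency); the alternative
`weight_mode="r_diff"` uses r_R − r_S clipped to [−1, 1]. Ties in hub
ranking break lexicographically.

## Synthetic generator

Each planted module is a single-factor Gaussian block: gene g in module m
under condition c is x_g = μ + σ·(√ρ_c[m]·f_m + √(1−ρ_c[m])·ε_g) with f_m
and ε_g independent standard normals, so the expected within-module
correlation is exactly ρ_c[m] and background genes are independent noise.
Values sit on a vst-like scale (μ = 8, σ = 1) purely for realism — Pearson
correlation is scale-free. Defaults mirror the study design: n = 6 samples
per condition (2 replicates × 3 time points), sample names `R_t1_a` etc.
Module genes are exchangeable by construction; the optional `hub_rho`
field gives the first gene of each module a higher factor loading, planting
a distinguished hub for connectivity-recovery tests. The count generator
assigns each gene an exact number of zero samples (cycled from
`zero_fraction_targets`), making retention under the "≥ 1 count in at
least half the samples" filter deterministic per gene.

What the generator does **not** emulate: negative-binomial count noise and
the DESeq2 vst (the pipeline contract is "normalised expression in";
`log_normalize` provides a median-of-ratios log2 fallback), temporal
autocorrelation (the analysis pools across time anyway), and
heavier-tailed or outlier-contaminated expression. Passing tests therefore
demonstrate correctness of the statistics and the recovery machinery under
the stated correlation model, not robustness to every artefact of real
RNAseq.

## Choice of problem sizes

Calibration runs use the study's n = 6 (where correlation estimates are
noisy and the lfdr must stay quiet on null data); recovery runs use n = 50
per condition, because at n = 6 single-pair correlation estimates are far
too noisy for deterministic module recovery — the separation keeps "is the
method correct" distinct from "does the study have power". The planted
recovery design is 3 × 40-gene modules with ρ_R = 0.8, ρ_S = 0 and no
background; the power measurement uses one 40-gene module plus 80
background genes so the lfdr's null-dominated-centre assumption holds (a
design in which *every* pair is differential has no empirical null to
estimate).

## Numerical and edge-case decisions

- Pearson (not Spearman) correlation, consistent with the normal theory
  behind the Fisher machinery.
- |r| ≥ 1 (duplicate-gene pairs) is clipped to magnitude 1 − 10⁻¹⁵ before
  the Fisher transform, with a warning — never an exception. The unit
  diagonal is masked out of the transform entirely.
- Zero-variance genes are dropped (with a report entry) at marker
  intersection; one reaching the correlation stage is an error naming the
  gene.
- Gene identifiers are canonicalised by uppercase/strip exact match;
  duplicate rows keep the highest total with a warning.
- "At least half the samples" is a ≥ comparison: boundary genes are
  retained.
- Interaction-edge confidences on a 0–1000 scale are auto-detected
  (max > 1) and rescaled; the > 0.85 filter is strict, and tables without
  scores pass unfiltered. TF-target edges are undirected for ego
  extraction.
- Edges are stored once with lexicographically ordered gene names and the
  table sorted by (gene_a, gene_b); combined with a single seed for all
  randomness this makes full pipeline runs byte-identical.

## Known limitations

- With very small n and strongly coupled modules, all within-module pairs
  share the module factor's sampling fluctuation, so their δ values move
  together; an identical-ρ module can occasionally produce a cluster of
  spuriously significant edges at n = 6 even though each pair is
  marginally null. This is a property of correlated test statistics, not
  of the estimator; it fades quickly with n.
- The lfdr needs a null-dominated centre; designs where most pairs are
  differential will inflate the fitted null and lose power (by design —
  the alternative is anti-conservative).
- TOM module detection has the usual hierarchical-clustering failure
  modes on modules of very unequal density; the dynamic-cut parameters
  (quantile 0.99, min size 20) are exposed in the config.
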