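# diffconet

Differential co-expression network analysis between two conditions — for
systems biologists asking not *which genes change in abundance* but *which
gene pairs change how they co-vary*. The motivating setting is a pair of
HER2+ breast-cancer cell lines (trastuzumab-resistant "R" vs sensitive
"S") profiled by RNAseq over a short ligand-stimulation time course
(2 replicates × 3 time points, so n = 6 samples per condition), where the
rewiring of hypoxia/NF-κB co-expression — rather than differential
expression — separates the resistant from the sensitive state.

## The statistic

For every gene pair, Pearson correlations r_R and r_S are computed within
each condition and variance-stabilised with Fisher's transform
z = ½·ln((1+r)/(1−r)). The standardised difference

    δ = (z_R − z_S) / √( 1/(n_R − 3) + 1/(n_S − 3) )

is approximately N(0, 1) when the pair co-varies identically in both
conditions. Rather than a raw p-value cutoff, edges are selected by the
**local false discovery rate**: a Grenander (monotone) density estimate of
the observed |δ| is combined with a half-normal empirical null (scale
fitted by truncated maximum likelihood on the central portion, null
proportion η₀ by censoring) into lfdr(δ) = η₀·f₀(|δ|)/f(|δ|). Edges with
lfdr < 0.05 form the differential network; sign +1 marks pairs more
correlated in R.

The scaled matrix A = |δ|/max|δ| is clustered by the topological overlap
measure (TOM) with average-linkage hierarchical clustering and a dynamic
branch cut. Hubs within a module M are ranked by **signed connectivity**

    kWithin(u) = conn⁺(u) − conn⁻(u),

the sum of u's positive intramodular significant edge weights minus the
absolute sum of its negative ones, with weights sign(δ)·|δ|/max|δ| ∈ [−1, 1].

A planted-module synthetic generator (single-factor Gaussian blocks with
exact expected within-module correlation) provides ground truth, so every
stage is testable without external data.

## Worked example

```bash
python analysis/01_simulate.py              # plant 3 differential modules
python analysis/03_differential_network.py  # edges -> lfdr -> modules -> hubs
python analysis/04_modules_and_hubs.py      # recovery and hub ranking
```

`03_differential_network.py` prints the run manifest:

```
"n_genes_analyzed": 120,
"n_pairs_evaluated": 7140,
"n_nodes": 120,
"n_significant_edges": 2011,
"n_modules": 3,
"module_sizes": {"1": 40, "2": 40, "3": 40}
```

All 7140 gene pairs are evaluated; 2011 survive lfdr < 0.05, every node
carries at least one significant edge, and the three detected modules
coincide exactly with the three planted 40-gene blocks —
`04_modules_and_hubs.py` reports `adjusted Rand index vs planted modules:
1.000` and lists each module's top-5 kWithin hubs. Because the planted
blocks are correlated in R and independent in S, every within-module edge
carries sign +1 (higher correlation in the resistant condition).

The same thing from the command line:

```bash
diffconet simulate --n-genes 120 --module-sizes 40,40,40 \
    --rho-r 0.8,0.8,0.8 --rho-s 0,0,0 --n-samples 50 --seed 11 --out data/
diffconet diffnet --expr-r data/expr_R.tsv --expr-s data/expr_S.tsv \
    --out run/ --lfdr 0.05
diffconet report run/manifest.json
```

Subcommands: `simulate`, `filter` (count-retention: ≥ 1 count in at least
half the samples), `diffnet`, `modules`, `subnet` (PPI/TF-target merging,
induced and ego subnetworks), `report`.

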