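#!/usr/bin/env python
"""Simulate the two-condition study design with planted differential modules.

Generates the dataset the rest of the analysis runs on: 120 genes, three
40-gene modules that are strongly co-expressed (rho = 0.8) in the resistant
condition "R" and uncorrelated in the sensitive condition "S", observed at
n = 50 samples per condition (power scale for recovery; the calibration
analyses use the study's n = 6 separately).  A raw count matrix with a
controlled fraction of low-count genes is written for the filtering step.
"""

from pathlib import Path

from diffconet.io import write_matrix
from diffconet.synthetic import SyntheticSpec, generate_count_matrix, generate_expression_pair

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 11

SPEC = SyntheticSpec(
    n_genes=120,
    module_sizes=[40, 40, 40],
    rho_R=[0.8, 0.8, 0.8],
    rho_S=[0.0, 0.0, 0.0],
    n_samples_R=50,
    n_samples_S=50,
    seed=SEED,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr_r, expr_s, truth = generate_expression_pair(SPEC)
    write_matrix(expr_r, OUT / "expr_R.tsv")
    write_matrix(expr_s, OUT / "expr_S.tsv")
    truth.labels.to_frame().to_csv(OUT / "ground_truth.tsv", sep="\t")

    # counts for the retention-filter demonstration: 30% of genes are
    # zero in 80% of samples and must be removed by the filter
    counts = generate_count_matrix(
        1000, 20, zero_fraction_targets=[0.8] * 3 + [0.2] * 7, seed=SEED
    )
    write_matrix(counts, OUT / "counts.tsv")

    print(f"wrote expression pair ({SPEC.n_genes} genes x {SPEC.n_samples_R} samples/condition)")
    print(f"planted modules: {SPEC.module_sizes}, rho_R={SPEC.rho_R}, rho_S={SPEC.rho_S}")
    print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples -> {OUT}")


if __name__ == "__main__":
    main()
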