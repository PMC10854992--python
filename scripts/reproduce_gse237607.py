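#!/usr/bin/env python
"""Reproduce the EGF differential network from the deposited GEO series.

This helper is NOT part of the test surface: it needs network access (or a
prior manual download) of series GSE237607 plus the 515-gene hypoxia/NF-kB
marker list, neither of which ships with the package.

Expected workflow:

1. Download the supplementary raw count matrices for the BT474 (sensitive,
   "S") and BT474R (resistant, "R") cell lines from
   https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSE237607
   and export them as TSV (genes x samples).
2. Normalise each matrix (vst via DESeq2 is what the study used; this
   script falls back to the package's median-of-ratios log-normalisation).
3. Select the 6 EGF-treated samples per condition (2 replicates x 3 time
   points) by the sample-name patterns given on the command line.
4. Run the differential pipeline restricted to the marker list and compare
   the resulting node/edge/module counts with the published figures
   (385/515 markers present, 341 nodes, 2980 significant edges, 3 modules,
   largest module n = 148).

Example:

    python scripts/reproduce_gse237607.py \
        --counts-r BT474R_counts.tsv --counts-s BT474_counts.tsv \
        --sample-pattern-r EGF --sample-pattern-s EGF \
        --markers hypoxia_nfkb_515.txt --out results/gse237607
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from diffconet.io import read_marker_list, read_matrix, write_matrix
from diffconet.pipeline import PipelineConfig, run_differential_pipeline
from diffconet.preprocessing import filter_low_counts, log_normalize


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--counts-r", required=True, help="BT474R raw counts TSV")
    parser.add_argument("--counts-s", required=True, help="BT474 raw counts TSV")
    parser.add_argument("--expr-r", help="pre-normalised (vst) BT474R expression TSV")
    parser.add_argument("--expr-s", help="pre-normalised (vst) BT474 expression TSV")
    parser.add_argument("--sample-pattern-r", default="EGF")
    parser.add_argument("--sample-pattern-s", default="EGF")
    parser.add_argument("--markers", required=True, help="515-gene marker list, one per line")
    parser.add_argument("--out", required=True)
    args = parser.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    if args.expr_r and args.expr_s:
        expr_paths = {"R": Path(args.expr_r), "S": Path(args.expr_s)}
    else:
        expr_paths = {}
        for cond, path, pattern in (
            ("R", args.counts_r, args.sample_pattern_r),
            ("S", args.counts_s, args.sample_pattern_s),
        ):
            counts = read_matrix(path)
            counts = counts.loc[:, [c for c in counts.columns if pattern in c]]
            if counts.shape[1] != 6:
                print(
                    f"warning: expected 6 EGF samples for condition {cond}, "
                    f"got {counts.shape[1]} matching {pattern!r}"
                )
            kept = filter_low_counts(counts)  # >=1 count in at least half the samples
            expr = log_normalize(kept)
            expr_paths[cond] = out / f"expr_{cond}.tsv"
            write_matrix(expr, expr_paths[cond])

    markers = read_marker_list(args.markers)
    manifest = run_differential_pipeline(
        PipelineConfig(
            out_dir=str(out / "diffnet"),
            expr_r=str(expr_paths["R"]),
            expr_s=str(expr_paths["S"]),
            markers=args.markers,
            seed=0,
        )
    )
    summary = {
        "markers_supplied": len(markers),
        "markers_analyzable": manifest["marker_report"]["n_analyzable"],
        "n_nodes": manifest["n_nodes"],
        "n_significant_edges": manifest["n_significant_edges"],
        "n_modules": manifest["n_modules"],
        "largest_module": max(manifest["module_sizes"].values(), default=0),
        "published_reference": {
            "markers_analyzable": 385,
            "n_nodes": 341,
            "n_significant_edges": 2980,
            "n_modules": 3,
            "largest_module": 148,
        },
    }
    with open(out / "reproduction_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
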