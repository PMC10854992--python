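"""End-to-end orchestration of the differential co-expression pipeline.

A single config drives: marker intersection -> per-condition correlation ->
Fisher-z delta statistics with joint local-FDR -> differential network ->
TOM module detection -> signed connectivity -> exports (edge table, module
table, GraphML, Cytoscape TSV) plus a JSON run manifest capturing input
hashes, parameters and the node/edge/module counts, so a run can be
reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffcorr import build_edge_table, correlation_matrix
from .io import write_differential_edges, write_module_table
from .network import (
    DifferentialNetwork,
    delta_matrix_from_edges,
    detect_modules,
    module_summary,
    scale_delta_matrix,
    signed_connectivity,
    topological_overlap,
)
from .preprocessing import MarkerList, intersect_markers
from .synthetic import SyntheticSpec, generate_expression_pair

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_differential_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative run description; exactly one of file inputs or synthetic spec."""

    out_dir: str
    expr_r: str | None = None
    expr_s: str | None = None
    synthetic: dict | None = None
    markers: str | None = None
    lfdr_threshold: float = 0.05
    min_module_size: int = 20
    cut_method: str = "dynamic"
    n_modules: int | None = None
    weight_mode: str = "scaled_delta"
    lfdr_input: str = "delta"
    cluster_scope: str = "all"  # "all" analysed genes, or "significant" nodes only
    seed: int = 0

    def validate(self) -> None:
        file_input = self.expr_r is not None and self.expr_s is not None
        if file_input == (self.synthetic is not None):
            raise ValueError(
                "provide exactly one of (expr_r + expr_s) file inputs or a synthetic spec"
            )
        if not (0.0 < self.lfdr_threshold < 1.0):
            raise ValueError(f"lfdr_threshold must be in (0, 1), got {self.lfdr_threshold}")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be positive")
        if self.cluster_scope not in ("all", "significant"):
            raise ValueError(f"unknown cluster_scope {self.cluster_scope!r}")
        if self.lfdr_input not in ("delta", "pvalue"):
            raise ValueError(f"unknown lfdr_input {self.lfdr_input!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig):
    from .io import read_matrix

    hashes = {}
    if config.synthetic is not None:
        spec_fields = dict(config.synthetic)
        spec_fields.setdefault("seed", config.seed)
        spec = SyntheticSpec(**spec_fields)
        expr_r, expr_s, _ = generate_expression_pair(spec)
        hashes["synthetic_spec"] = hashlib.sha256(
            json.dumps(asdict(spec), sort_keys=True).encode()
        ).hexdigest()
    else:
        expr_r = read_matrix(config.expr_r)
        expr_s = read_matrix(config.expr_s)
        hashes["expr_r"] = _sha256(Path(config.expr_r))
        hashes["expr_s"] = _sha256(Path(config.expr_s))
    return expr_r, expr_s, hashes


def run_differential_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns (and writes) the JSON run manifest.

    Any stage error aborts with the stage name; partially written outputs
    are removed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load_inputs"
    try:
        expr_r, expr_s, hashes = _load_inputs(config)

        stage = "intersect_markers"
        if config.markers:
            from .io import read_marker_list

            markers = read_marker_list(config.markers)
            hashes["markers"] = _sha256(Path(config.markers))
        else:
            markers = MarkerList(list(expr_r.index))
        expr_r, expr_s, marker_report = intersect_markers(expr_r, expr_s, markers)

        stage = "correlation"
        set_r = correlation_matrix(expr_r, condition="R")
        set_s = correlation_matrix(expr_s, condition="S")

        stage = "delta_lfdr"
        edges, fit = build_edge_table(
            set_r, set_s, lfdr_threshold=config.lfdr_threshold, lfdr_input=config.lfdr_input
        )

        stage = "network"
        genes = set_r.genes
        dmat = delta_matrix_from_edges(edges, genes)
        adjacency = scale_delta_matrix(dmat)
        network = DifferentialNetwork(
            genes=genes,
            adjacency=adjacency,
            edges=edges[edges["significant"]].reset_index(drop=True),
            all_edges=edges,
        )

        stage = "modules"
        if config.cluster_scope == "significant":
            keep = [g in set(network.nodes) for g in genes]
            idx = np.flatnonzero(keep)
            sub_tom = topological_overlap(adjacency[np.ix_(idx, idx)])
            sub_labels = detect_modules(
                sub_tom,
                min_module_size=config.min_module_size,
                method=config.cut_method,
                n_modules=config.n_modules,
            )
            labels_arr = np.zeros(len(genes), dtype=int)
            labels_arr[idx] = sub_labels
        else:
            tom = topological_overlap(adjacency)
            labels_arr = detect_modules(
                tom,
                min_module_size=config.min_module_size,
                method=config.cut_method,
                n_modules=config.n_modules,
            )
        labels = pd.Series(labels_arr, index=genes, name="module")
        # a module of a differential network must carry differential signal:
        # detected branches with no significant intramodular edge are unassigned
        sig_edges = edges[edges["significant"]]
        la_sig = labels.loc[sig_edges["gene_a"]].to_numpy()
        lb_sig = labels.loc[sig_edges["gene_b"]].to_numpy()
        with_signal = set(la_sig[(la_sig == lb_sig) & (la_sig > 0)])
        labels[~labels.isin(with_signal)] = 0
        # relabel by decreasing size so colour ranks stay contiguous
        kept = sorted(set(labels) - {0}, key=lambda m: (-(labels == m).sum(), m))
        labels = labels.map({m: i for i, m in enumerate(kept, start=1)}).fillna(0).astype(int)

        stage = "connectivity"
        kwithin = signed_connectivity(edges, labels, weight_mode=config.weight_mode)
        summary = module_summary(edges, labels, kwithin)

        stage = "export"
        sig = edges[edges["significant"]]
        intra_counts = pd.Series(0, index=genes, dtype=int)
        la = labels.loc[sig["gene_a"]].to_numpy()
        lb = labels.loc[sig["gene_b"]].to_numpy()
        intra_mask = (la == lb) & (la > 0)
        for g in pd.concat([sig["gene_a"][intra_mask], sig["gene_b"][intra_mask]]):
            intra_counts[g] += 1
        module_table = pd.DataFrame(
            {
                "gene": genes,
                "module": labels.to_numpy(),
                "kWithin": kwithin.loc[genes].to_numpy(),
                "n_intramodular_edges": intra_counts.loc[genes].to_numpy(),
            }
        )
        paths = {
            "edges": out_dir / "edges.tsv",
            "modules": out_dir / "modules.tsv",
            "module_summary": out_dir / "module_summary.tsv",
            "graphml": out_dir / "network.graphml",
            "cytoscape": out_dir / "cytoscape_edges.tsv",
            "manifest": out_dir / "manifest.json",
        }
        written = list(paths.values())
        write_differential_edges(edges, paths["edges"])
        write_module_table(module_table, paths["modules"])
        summary.to_csv(paths["module_summary"], sep="\t", index=False)
        network.write_graphml(paths["graphml"])
        network.write_cytoscape_tsv(paths["cytoscape"])

        manifest = {
            "version": __version__,
            "parameters": {
                k: v for k, v in asdict(config).items() if k not in ("out_dir",)
            },
            "input_hashes": hashes,
            "marker_report": {
                k: (v if isinstance(v, (int, float)) else len(v))
                for k, v in marker_report.items()
            },
            "n_genes_analyzed": len(genes),
            "n_pairs_evaluated": int(len(edges)),
            "n_nodes": len(network.nodes),
            "n_significant_edges": int(edges["significant"].sum()),
            "n_modules": int(len(set(labels) - {0})),
            "module_sizes": {int(m): int((labels == m).sum()) for m in sorted(set(labels) - {0})},
            "eta0": float(fit.eta0),
            "outputs": {k: str(v) for k, v in paths.items()},
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        for p in written:
            try:
                Path(p).unlink(missing_ok=True)
            except OSError:
                pass
        raise PipelineError(stage, exc) from exc
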