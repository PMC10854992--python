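"""Merged PPI / TF-target interaction networks and subnetwork extraction.

Edge lists from different sources (protein-protein interactions, TF-target
relations) are merged into one undirected network with per-edge source tags
and a confidence filter (strictly greater than the threshold, matching the
"very high confidence (>0.85)" convention).  Downstream extraction covers
gene-set-induced subnetworks (e.g. the DEG superset) and ego neighbourhoods
(e.g. the 1-step neighbourhood of IRF1).  TF-target edges are treated as
undirected so ego extraction captures both upstream and downstream
interactors.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "merge_networks",
    "induced_subnetwork",
    "ego_subnetwork",
    "presence_filter",
    "write_interaction_tsv",
]


def _normalise_confidence(conf: pd.Series) -> pd.Series:
    """Rescale 0-1000 style scores to [0, 1] (detected by max > 1)."""
    c = pd.to_numeric(conf, errors="coerce")
    if c.max() > 1.0:
        c = c / 1000.0
    return c


def merge_networks(
    edge_lists: list[pd.DataFrame], min_confidence: float = 0.85
) -> nx.Graph:
    """Merge edge tables into one undirected network.

    Edges require confidence strictly above ``min_confidence``; tables
    without a confidence column pass unfiltered.  Duplicate edges collapse
    to one keeping the maximum confidence and the union of source tags;
    self-loops and malformed rows are skipped with a warning.
    """
    net = nx.Graph()
    kept_any = False
    for t, table in enumerate(edge_lists):
        df = table.copy()
        if "confidence" in df.columns:
            df["confidence"] = _normalise_confidence(df["confidence"])
        source_default = f"list{t}"
        for idx, row in df.iterrows():
            a = str(row.get("node_a", "")).strip()
            b = str(row.get("node_b", "")).strip()
            if not a or not b or a == "nan" or b == "nan":
                logger.warning("skipping malformed row %s of table %d", idx, t)
                continue
            if a == b:
                logger.warning("skipping self-loop %s in table %d", a, t)
                continue
            conf = row.get("confidence")
            if conf is not None and pd.notna(conf):
                conf = float(conf)
                if not conf > min_confidence:
                    continue
            else:
                conf = None
            source = str(row.get("source", source_default) or source_default)
            u, v = sorted((a, b))
            if net.has_edge(u, v):
                data = net[u][v]
                data["sources"].add(source)
                if conf is not None:
                    data["confidence"] = max(data.get("confidence") or 0.0, conf)
            else:
                net.add_edge(u, v, sources={source}, confidence=conf)
            kept_any = True
    if not kept_any:
        raise ValueError("no valid edges after merging (all rows skipped or filtered)")
    return net


def induced_subnetwork(net: nx.Graph, gene_set: list[str]) -> nx.Graph:
    """Subnetwork induced by gene_set ∩ network nodes (edges inside only)."""
    nodes = [g for g in gene_set if net.has_node(g)]
    sub = net.subgraph(nodes).copy()
    logger.info(
        "induced subnetwork: %d/%d genes present, %d nodes, %d edges",
        len(nodes), len(gene_set), sub.number_of_nodes(), sub.number_of_edges(),
    )
    if sub.number_of_nodes() == 0:
        import warnings

        warnings.warn("induced subnetwork is empty", stacklevel=2)
    return sub


def ego_subnetwork(net: nx.Graph, seed_gene: str, radius: int = 1) -> nx.Graph:
    """Seed plus all nodes within graph distance <= radius, edges among them."""
    if not net.has_node(seed_gene):
        raise ValueError(f"seed gene {seed_gene!r} not present in the network")
    return nx.ego_graph(net, seed_gene, radius=radius).copy()


def presence_filter(net: nx.Graph, expressed_genes) -> nx.Graph:
    """Restrict a network to genes with expression quantification.

    Composition helper: ``presence_filter(ego_subnetwork(net, "IRF1"), expr.index)``
    realises "1-step interactors with some expression quantification".
    """
    present = set(map(str, expressed_genes))
    return net.subgraph([n for n in net.nodes if n in present]).copy()


def write_interaction_tsv(net: nx.Graph, path: str | Path) -> None:
    rows = []
    for u, v, data in sorted(net.edges(data=True)):
        rows.append(
            {
                "node_a": u,
                "node_b": v,
                "confidence": "" if data.get("confidence") is None else f"{data['confidence']:.6g}",
                "source": ";".join(sorted(data.get("sources", set()))),
            }
        )
    pd.DataFrame(rows, columns=["node_a", "node_b", "confidence", "source"]).to_csv(
        path, sep="\t", index=False
    )
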