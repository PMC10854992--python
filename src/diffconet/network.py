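"""Differential network assembly, TOM module detection and signed hub scoring.

The scaled |delta| matrix serves as a weighted adjacency in [0, 1]; the
topological overlap measure (TOM) turns it into a neighbourhood-aware
similarity that is clustered with average-linkage hierarchical clustering
and a dynamic branch cut.  Hubs within each module are ranked by signed
connectivity

    kWithin(u) = conn+(u) - conn-(u),

the sum of a node's positive intramodular significant edge weights minus
the absolute sum of its negative ones, with edge weights in [-1, 1]
(default: the signed scaled delta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "DifferentialNetwork",
    "delta_matrix_from_edges",
    "scale_delta_matrix",
    "topological_overlap",
    "detect_modules",
    "signed_connectivity",
    "largest_component",
    "hub_nodes",
    "module_summary",
]

# size-rank colour convention for module labels (label 0 = unassigned/grey)
MODULE_COLORS = [
    "grey", "turquoise", "blue", "brown", "yellow", "green", "red",
    "black", "pink", "magenta", "purple", "greenyellow", "tan",
]


@dataclass
class DifferentialNetwork:
    """Node set, significant edges and the full scaled |delta| adjacency.

    The adjacency covers ALL analysed genes (clustering operates on the
    full scaled matrix); ``nodes`` lists only genes carrying at least one
    significant edge, matching how network size is conventionally reported.
    """

    genes: list[str]
    adjacency: np.ndarray
    edges: pd.DataFrame  # significant edges only
    all_edges: pd.DataFrame = field(repr=False, default=None)

    @property
    def nodes(self) -> list[str]:
        present = set(self.edges["gene_a"]) | set(self.edges["gene_b"])
        return [g for g in self.genes if g in present]

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.gene_a,
                row.gene_b,
                delta=float(row.delta),
                lfdr=float(row.lfdr),
                sign=int(row.sign),
            )
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))

    def write_cytoscape_tsv(self, path: str | Path) -> None:
        """Cytoscape-compatible edge list: source, target, weight, sign, lfdr."""
        max_abs = float(np.abs(self.all_edges["delta"]).max()) if len(self.all_edges) else 0.0
        weight = self.edges["delta"] / max_abs if max_abs > 0 else self.edges["delta"] * 0.0
        out = pd.DataFrame(
            {
                "source": self.edges["gene_a"],
                "target": self.edges["gene_b"],
                "weight": weight.map(lambda x: f"{x:.6g}"),
                "sign": self.edges["sign"],
                "lfdr": self.edges["lfdr"].map(lambda x: f"{x:.6g}"),
            }
        )
        out.to_csv(path, sep="\t", index=False)


def delta_matrix_from_edges(edges: pd.DataFrame, genes: list[str]) -> np.ndarray:
    """Symmetric delta matrix over ``genes`` from the per-pair edge table."""
    index = {g: i for i, g in enumerate(genes)}
    d = np.zeros((len(genes), len(genes)))
    ia = edges["gene_a"].map(index).to_numpy()
    ib = edges["gene_b"].map(index).to_numpy()
    d[ia, ib] = edges["delta"].to_numpy()
    d[ib, ia] = edges["delta"].to_numpy()
    return d


def scale_delta_matrix(delta: np.ndarray) -> np.ndarray:
    """A_ij = |delta_ij| / max|delta|, diagonal zero; zero matrix if max is 0."""
    delta = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("delta matrix must be finite")
    if not np.allclose(delta, delta.T):
        raise ValueError("delta matrix must be symmetric")
    a = np.abs(delta).astype(float)
    np.fill_diagonal(a, 0.0)
    m = a.max()
    if m > 0:
        a = a / m
    return a


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned weighted topological overlap.

    TOM_ij = (sum_u A_iu*A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij) for
    i != j with k_i the weighted degree; TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    min_module_size: int = 20,
    method: str = "dynamic",
    n_modules: int | None = None,
    cut_quantile: float = 0.99,
) -> np.ndarray:
    """Module labels from average-linkage clustering of dissimilarity 1 - TOM.

    The default dynamic cut places the height at the ``cut_quantile``
    quantile of merge heights (capped just below 1 so branches that only
    join at full dissimilarity stay apart); branches smaller than
    ``min_module_size`` merge into the retained module with the highest
    mean TOM when that exceeds the global mean off-diagonal overlap,
    otherwise they get label 0.  Labels are positive integers in
    decreasing module-size order; deterministic, ties broken by the lowest
    gene index in the module.
    """
    n = tom.shape[0]
    if n < 3:
        warnings.warn("fewer than 3 genes; assigning a single module", stacklevel=2)
        return np.ones(n, dtype=int)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    if method == "fixed_k":
        if not n_modules:
            raise ValueError("fixed_k cut requires n_modules")
        raw = fcluster(z, t=n_modules, criterion="maxclust")
    elif method == "dynamic":
        heights = z[:, 2]
        cut_h = min(float(np.quantile(heights, cut_quantile)), 1.0 - 1e-3)
        raw = fcluster(z, t=cut_h, criterion="distance")
    else:
        raise ValueError(f"unknown cut method {method!r}")

    clusters: dict[int, np.ndarray] = {
        c: np.flatnonzero(raw == c) for c in np.unique(raw)
    }
    big = [c for c, members in clusters.items() if members.size >= min_module_size]
    small = [c for c in clusters if c not in set(big)]
    # order retained modules by decreasing size, ties by lowest gene index
    big.sort(key=lambda c: (-clusters[c].size, clusters[c].min()))

    labels = np.zeros(n, dtype=int)
    for new_label, c in enumerate(big, start=1):
        labels[clusters[c]] = new_label

    if small and big:
        off_diag = tom[~np.eye(n, dtype=bool)]
        merge_floor = float(off_diag.mean())
        for c in sorted(small, key=lambda c: clusters[c].min()):
            members = clusters[c]
            affinities = [
                tom[np.ix_(members, clusters[b])].mean() for b in big
            ]
            best = int(np.argmax(affinities))
            if affinities[best] > merge_floor:
                labels[members] = best + 1
    return labels


def _edge_weights(edges: pd.DataFrame, weight_mode: str) -> np.ndarray:
    if weight_mode == "scaled_delta":
        deltas = edges["delta"].to_numpy(dtype=float)
        max_abs = np.abs(deltas).max() if deltas.size else 0.0
        return deltas / max_abs if max_abs > 0 else deltas
    if weight_mode == "r_diff":
        return np.clip(
            edges["r_R"].to_numpy(dtype=float) - edges["r_S"].to_numpy(dtype=float),
            -1.0,
            1.0,
        )
    raise ValueError(f"unknown weight_mode {weight_mode!r}")


def signed_connectivity(
    edges: pd.DataFrame,
    labels: pd.Series,
    weight_mode: str = "scaled_delta",
) -> pd.Series:
    """kWithin(u) = conn+(u) - conn-(u) over significant intramodular edges.

    conn+ is the sum of a node's positive intramodular edge weights and
    conn- the absolute sum of its negative ones.  Weights are the signed
    scaled delta by default (``weight_mode="r_diff"`` uses the raw
    correlation difference clipped to [-1, 1]).  The weight scaling uses
    the maximum |delta| over the FULL edge table so weights match the
    network adjacency.
    """
    missing = (set(edges["gene_a"]) | set(edges["gene_b"])) - set(labels.index)
    if missing:
        raise ValueError(f"unlabeled edge endpoint(s): {sorted(missing)[:10]}")
    weights = _edge_weights(edges, weight_mode)
    conn_pos = pd.Series(0.0, index=labels.index)
    conn_neg = pd.Series(0.0, index=labels.index)
    sig = edges["significant"].to_numpy(dtype=bool)
    ga, gb = edges["gene_a"].to_numpy(), edges["gene_b"].to_numpy()
    la = labels.loc[ga].to_numpy()
    lb = labels.loc[gb].to_numpy()
    intra = sig & (la == lb) & (la > 0)
    for g_u, g_v, w in zip(ga[intra], gb[intra], weights[intra]):
        if w >= 0:
            conn_pos[g_u] += w
            conn_pos[g_v] += w
        else:
            conn_neg[g_u] += -w
            conn_neg[g_v] += -w
    kwithin = conn_pos - conn_neg
    kwithin.name = "kWithin"
    return kwithin


def largest_component(
    network: DifferentialNetwork, labels: pd.Series, module_label: int
) -> set[str]:
    """Nodes of the largest connected component of a module's significant edges.

    Ties are broken by the smallest lexicographic node name.
    """
    members = set(labels.index[labels == module_label])
    if not members:
        raise ValueError(f"module {module_label} does not exist")
    sub = [
        (a, b)
        for a, b in zip(network.edges["gene_a"], network.edges["gene_b"])
        if a in members and b in members
    ]
    if not sub:
        warnings.warn(f"module {module_label} has no significant edges", stacklevel=2)
        return set()
    g = nx.Graph(sub)
    components = sorted(
        nx.connected_components(g), key=lambda c: (-len(c), min(c))
    )
    return set(components[0])


def hub_nodes(kwithin: pd.Series, top_n: int) -> list[str]:
    """Genes ranked by kWithin descending, ties broken by name."""
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    ranked = sorted(kwithin.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:top_n]]


def module_summary(
    edges: pd.DataFrame, labels: pd.Series, kwithin: pd.Series
) -> pd.DataFrame:
    """Per-module size, intramodular significant edge count and colour name."""
    rows = []
    sig = edges[edges["significant"]]
    la = labels.reindex(sig["gene_a"]).to_numpy()
    lb = labels.reindex(sig["gene_b"]).to_numpy()
    for m in sorted(set(labels) - {0}):
        n_intra = int(np.sum((la == m) & (lb == m)))
        rows.append(
            {
                "module": m,
                "color": MODULE_COLORS[m] if m < len(MODULE_COLORS) else f"module{m}",
                "size": int((labels == m).sum()),
                "n_intramodular_edges": n_intra,
                "max_kWithin": float(kwithin[labels == m].max()) if (labels == m).any() else 0.0,
            }
        )
    return pd.DataFrame(rows)
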