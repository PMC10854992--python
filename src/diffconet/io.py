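"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression and count matrices travel as TSV/CSV with genes as rows and a
leading ``gene`` column; marker lists are one symbol per line (``#`` starts
a comment); interaction edge lists are TSV with columns
``node_a, node_b[, confidence][, source]``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_marker_list",
    "write_marker_list",
    "read_interaction_edges",
    "write_differential_edges",
    "write_module_table",
]

EDGE_COLUMNS = [
    "gene_a",
    "gene_b",
    "r_R",
    "r_S",
    "z_R",
    "z_S",
    "delta",
    "p_value",
    "lfdr",
    "significant",
    "sign",
]


def read_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a gene-by-sample matrix; delimiter sniffed unless ``sep`` given."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_marker_list(path: str | Path, provenance: str = "") -> "MarkerList":
    from .preprocessing import MarkerList

    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return MarkerList(symbols, provenance=provenance or str(path))


def write_marker_list(symbols: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(symbols) + "\n")


def read_interaction_edges(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read an interaction edge table (node_a, node_b[, confidence][, source])."""
    df = pd.read_csv(path, sep=sep)
    required = {"node_a", "node_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge table {path} lacks columns {sorted(required - set(df.columns))}")
    return df


def _format_float(x: float) -> str:
    return f"{x:.6g}"


def write_differential_edges(edges: pd.DataFrame, path: str | Path) -> None:
    """Write the differential edge table with the canonical column order.

    Floats at 6 significant digits; ``significant`` rendered true/false.
    """
    out = edges[EDGE_COLUMNS].copy()
    for col in ("r_R", "r_S", "z_R", "z_S", "delta", "p_value", "lfdr"):
        out[col] = out[col].map(_format_float)
    out["significant"] = out["significant"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


def write_module_table(modules: pd.DataFrame, path: str | Path) -> None:
    """Write gene, module, kWithin, n_intramodular_edges."""
    out = modules[["gene", "module", "kWithin", "n_intramodular_edges"]].copy()
    out["kWithin"] = out["kWithin"].map(_format_float)
    out.to_csv(path, sep="\t", index=False)
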