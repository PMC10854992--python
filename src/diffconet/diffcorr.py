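"""Per-pair differential correlation statistics between two conditions.

For each gene pair the Pearson correlation is computed separately in the
resistant (R) and sensitive (S) condition, variance-stabilised by Fisher's
transformation z = 0.5*ln((1+r)/(1-r)), and compared with the standardised
difference

    delta = (z_R - z_S) / sqrt(1/(n_R - 3) + 1/(n_S - 3)),

which is approximately N(0, 1) for a null pair.  Significance is assessed
with the local false discovery rate computed over all pairs jointly; edges
with lfdr below the threshold (strict) form the differential network.  The
sign convention is +1 when the pair is more correlated in R.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lfdr import LfdrFit, local_fdr

__all__ = [
    "CorrelationSet",
    "correlation_matrix",
    "fisher_z",
    "delta_statistic",
    "edge_pvalue",
    "build_edge_table",
]

_CLIP = 1.0 - 1e-15


@dataclass
class CorrelationSet:
    """Pearson correlations of one condition with their Fisher transform."""

    genes: list[str]
    r: np.ndarray
    z: np.ndarray
    n: int
    condition: str = ""

    def __post_init__(self) -> None:
        if not np.allclose(self.r, self.r.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")


def correlation_matrix(expr: pd.DataFrame, condition: str = "") -> CorrelationSet:
    """Pearson correlations across a condition's samples.

    Zero-variance genes must have been dropped upstream; one reaching this
    stage is an error naming the gene.
    """
    n = expr.shape[1]
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if np.any(sd == 0.0):
        bad = [g for g, s in zip(expr.index, sd) if s == 0.0]
        raise ValueError(f"zero-variance gene(s) reached correlation: {bad[:10]}")
    r = np.corrcoef(values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    # transform off-diagonal only: the unit diagonal is never an edge
    r_masked = r.copy()
    np.fill_diagonal(r_masked, 0.0)
    z = fisher_z(r_masked)
    np.fill_diagonal(z, 0.0)
    return CorrelationSet(genes=list(expr.index), r=r, z=z, n=n, condition=condition)


def fisher_z(r):
    """Fisher's variance-stabilising transform z = 0.5*ln((1+r)/(1-r)).

    Values with |r| >= 1 (duplicate-gene edge case) are clipped to
    magnitude 1 - 1e-15 with a warning, never an exception.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        warnings.warn("|r| >= 1 clipped before Fisher transform", stacklevel=2)
        arr = np.clip(arr, -_CLIP, _CLIP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def delta_statistic(z_r, z_s, n_r: int, n_s: int):
    """Standardised Fisher-z difference; requires n > 3 in both conditions."""
    if n_r <= 3 or n_s <= 3:
        raise ValueError(
            f"delta requires n > 3 in both conditions (variance 1/(n-3)); "
            f"got n_R={n_r}, n_S={n_s}"
        )
    denom = math.sqrt(1.0 / (n_r - 3) + 1.0 / (n_s - 3))
    return (np.asarray(z_r) - np.asarray(z_s)) / denom if not np.isscalar(z_r) else (
        (z_r - z_s) / denom
    )


def edge_pvalue(delta):
    """Two-sided normal p-value of delta: p = 2*(1 - Phi(|delta|))."""
    arr = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite delta")
    p = 2.0 * stats.norm.sf(np.abs(arr))
    return float(p) if np.isscalar(delta) else p


def build_edge_table(
    set_r: CorrelationSet,
    set_s: CorrelationSet,
    lfdr_threshold: float = 0.05,
    lfdr_input: str = "delta",
) -> tuple[pd.DataFrame, LfdrFit]:
    """One record per unordered gene pair with delta, p, lfdr and significance.

    The lfdr is computed over ALL pairs jointly, then ``significant`` is the
    strict comparison lfdr < threshold.  Gene names within each pair are
    ordered lexicographically; rows sorted by (gene_a, gene_b) so output is
    deterministic and invariant to input gene permutation.
    """
    if set_r.genes != set_s.genes:
        sym_diff = sorted(set(set_r.genes) ^ set(set_s.genes))
        if sym_diff:
            raise ValueError(f"gene sets differ between conditions: {sym_diff[:20]}")
        raise ValueError("gene order differs between conditions")
    genes = np.array(set_r.genes)
    iu, ju = np.triu_indices(len(genes), k=1)

    r_r, r_s = set_r.r[iu, ju], set_s.r[iu, ju]
    z_r, z_s = set_r.z[iu, ju], set_s.z[iu, ju]
    delta = delta_statistic(z_r, z_s, set_r.n, set_s.n)
    pvals = edge_pvalue(delta)
    if np.unique(delta).size == 1:
        # identical inputs (all deltas equal): no evidence against any null
        fit = LfdrFit(lfdr=np.ones_like(delta), eta0=1.0, sigma0=float("nan"))
    else:
        fit = local_fdr(pvals if lfdr_input == "pvalue" else delta, input_mode=lfdr_input)

    a, b = genes[iu], genes[ju]
    swap = a > b
    gene_a = np.where(swap, b, a)
    gene_b = np.where(swap, a, b)
    edges = pd.DataFrame(
        {
            "gene_a": gene_a,
            "gene_b": gene_b,
            "r_R": r_r,
            "r_S": r_s,
            "z_R": z_r,
            "z_S": z_s,
            "delta": delta,
            "p_value": pvals,
            "lfdr": fit.lfdr,
            "significant": fit.lfdr < lfdr_threshold,
            "sign": np.sign(delta).astype(int),
        }
    )
    edges = edges.sort_values(["gene_a", "gene_b"], kind="stable", ignore_index=True)
    return edges, fit
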