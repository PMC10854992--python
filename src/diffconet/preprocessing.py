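"""Count filtering, normalisation hand-off and marker-list intersection.

The differential-correlation stage expects normalised (vst- or log-scale)
expression; this module supplies the retention filter applied to raw counts
("at least 1 count in at least half the samples"), a median-of-ratios
log-normalisation convenience for when vst input is unavailable, and the
marker-list intersection that restricts both conditions to a common,
analysable gene set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerList",
    "canonicalize_genes",
    "filter_low_counts",
    "intersect_markers",
    "log_normalize",
]


def _canonical(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class MarkerList:
    """Ordered, canonicalised gene-symbol list with a provenance note."""

    symbols: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for s in self.symbols:
            c = _canonical(s)
            if c and c not in seen:
                seen[c] = None
        self.symbols = list(seen)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


def canonicalize_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Uppercase/strip gene ids; duplicates keep the highest-total row.

    Matching is exact string match after canonicalisation; when duplicates
    collide the row with the largest total (count or expression sum) wins,
    with a logged warning.
    """
    out = df.copy()
    out.index = [_canonical(g) for g in out.index]
    if out.index.has_duplicates:
        dups = sorted(set(out.index[out.index.duplicated()]))
        logger.warning(
            "%d duplicate gene id(s) after canonicalization (%s...); keeping highest-total rows",
            len(dups),
            ", ".join(dups[:5]),
        )
        totals = out.sum(axis=1).to_numpy()
        order = np.argsort(-totals, kind="stable")
        out = out.iloc[order]
        out = out[~out.index.duplicated(keep="first")]
        out = out.loc[[g for g in dict.fromkeys([_canonical(i) for i in df.index]) if g in out.index]]
    out.index.name = "gene"
    return out


def filter_low_counts(
    counts: pd.DataFrame, min_count: int = 1, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Retain genes with >= min_count in at least min_fraction of samples.

    "At least half" is a >= comparison: a gene hitting the boundary exactly
    (e.g. 2 of 4 samples) is retained.  Gene order and the sample set are
    unchanged; the filter is idempotent.
    """
    if counts.size == 0:
        raise ValueError("empty count matrix")
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.isfinite(values)) or np.any(values != np.round(values)):
            raise ValueError("count matrix must contain non-negative integers")
        values = values.astype(np.int64)
    if np.any(values < 0):
        raise ValueError("count matrix must be non-negative")
    n_ok = (values >= min_count).sum(axis=1)
    keep = n_ok >= min_fraction * counts.shape[1]
    return counts.loc[keep]


def intersect_markers(
    expr_r: pd.DataFrame, expr_s: pd.DataFrame, markers: MarkerList
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Restrict both conditions to markers present in BOTH, in marker order.

    Zero-variance genes (constant in either condition) cannot enter the
    correlation stage and are dropped here with a logged warning.  The
    report lists markers missing from R, from S, or both, plus the dropped
    constant genes.
    """
    expr_r = canonicalize_genes(expr_r)
    expr_s = canonicalize_genes(expr_s)
    in_r, in_s = set(expr_r.index), set(expr_s.index)
    missing_r = [m for m in markers if m not in in_r]
    missing_s = [m for m in markers if m not in in_s]
    common = [m for m in markers if m in in_r and m in in_s]

    dropped_constant = []
    analyzable = []
    for g in common:
        if expr_r.loc[g].std() == 0.0 or expr_s.loc[g].std() == 0.0:
            dropped_constant.append(g)
        else:
            analyzable.append(g)
    if dropped_constant:
        logger.warning(
            "dropping %d zero-variance marker gene(s): %s",
            len(dropped_constant),
            ", ".join(dropped_constant[:10]),
        )
    if not analyzable:
        raise ValueError("no analyzable markers: empty intersection after filtering")
    report = {
        "n_markers": len(markers),
        "n_common": len(common),
        "n_analyzable": len(analyzable),
        "missing_from_R": missing_r,
        "missing_from_S": missing_s,
        "missing_from_both": [m for m in missing_r if m in set(missing_s)],
        "dropped_zero_variance": dropped_constant,
    }
    return expr_r.loc[analyzable], expr_s.loc[analyzable], report


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the gene-wise geometric mean.

    Only genes with no zero counts contribute; if none exist the caller
    falls back to total-count scaling.
    """
    values = counts.to_numpy(dtype=float)
    nonzero = np.all(values > 0, axis=1)
    if not nonzero.any():
        raise ValueError("no zero-free reference genes for median-of-ratios")
    ref = values[nonzero]
    log_geo_mean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def log_normalize(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount) per sample.

    Convenience fallback for when vst-normalised input is unavailable; the
    pipeline's contract is otherwise "normalised expression in".  When no
    gene is free of zeros, size factors degrade to total-count scaling with
    a warning.
    """
    if counts.size == 0:
        raise ValueError("empty count matrix")
    try:
        sf = size_factors(counts)
    except ValueError:
        logger.warning("no zero-free genes; falling back to total-count size factors")
        totals = counts.sum(axis=0).astype(float)
        sf = totals / math.exp(np.mean(np.log(totals)))
    normalized = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    return pd.DataFrame(
        np.log2(normalized + pseudocount), index=counts.index, columns=counts.columns
    )
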