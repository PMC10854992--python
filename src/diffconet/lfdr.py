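"""Local false discovery rate with an empirical half-normal null.

The differential-correlation statistic delta is approximately standard
normal for a null gene pair.  The local FDR of an observed value is the
posterior probability that the pair is null,

    lfdr(d) = eta0 * f0(|d|) / f(|d|),

where f is a Grenander (monotone non-increasing) density estimate of the
observed |delta|, f0 a half-normal null whose scale is fitted by truncated
maximum likelihood on the central portion of the data, and eta0 the null
proportion estimated by censoring at the same cutoff.  The estimator
assumes the centre of the statistic distribution is null-dominated (the
usual empirical-null assumption); outputs are clipped to [0, 1] and forced
monotone non-increasing in |delta| by isotonic regression.

A p-value input mode is also provided (Grenander density on p with a
uniform null), matching the convention where the tool is fed p-values
rather than z-scale statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from sklearn.isotonic import IsotonicRegression

__all__ = ["local_fdr", "grenander_density", "fit_halfnormal_null", "LfdrFit"]

_MIN_RECOMMENDED = 50


def grenander_density(x: np.ndarray, eval_at: np.ndarray | None = None) -> np.ndarray:
    """Grenander estimator: non-increasing density on [0, inf) at the data points.

    The estimate is the left derivative of the least concave majorant of the
    empirical CDF, computed by pool-adjacent-violators on the ECDF slopes.
    Returns densities aligned with ``eval_at`` (default: ``x`` itself).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("grenander_density expects non-negative values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    # collapse ties: support points and ECDF mass increments
    uniq, counts = np.unique(xs, return_counts=True)
    cdf = np.cumsum(counts) / n
    prev = np.concatenate(([0.0], uniq[:-1]))
    prev_cdf = np.concatenate(([0.0], cdf[:-1]))
    dx = uniq - prev
    if np.any(dx <= 0):  # only possible if uniq[0] == 0
        dx = np.maximum(dx, 1e-300)
    slopes = (cdf - prev_cdf) / dx
    # PAVA for non-increasing fit weighted by interval width
    iso = IsotonicRegression(increasing=False)
    fitted = iso.fit_transform(np.arange(uniq.size), slopes, sample_weight=dx)
    if eval_at is None:
        eval_at = x
    idx = np.searchsorted(uniq, np.asarray(eval_at, dtype=float), side="left")
    idx = np.clip(idx, 0, uniq.size - 1)
    return fitted[idx]


def fit_halfnormal_null(x_abs: np.ndarray, cutoff: float) -> float:
    """Truncated-ML scale of a half-normal null from values below ``cutoff``.

    Maximises the likelihood of |delta| <= cutoff under a half-normal
    truncated at the cutoff; robust to signal in the tails because only the
    central portion enters.
    """
    core = x_abs[x_abs <= cutoff]
    if core.size == 0 or cutoff <= 0:
        raise ValueError("no data below the truncation cutoff")
    sq = np.sum(core**2)
    m = core.size

    def nll(log_sigma: float) -> float:
        sigma = np.exp(log_sigma)
        # truncated half-normal: 2*phi(x/s)/s / (2*Phi(c/s) - 1)
        norm_const = 2.0 * stats.norm.cdf(cutoff / sigma) - 1.0
        return 0.5 * sq / sigma**2 + m * np.log(sigma) + m * np.log(norm_const)

    res = optimize.minimize_scalar(nll, bounds=(-7.0, 7.0), method="bounded")
    return float(np.exp(res.x))


class LfdrFit:
    """Result bundle: per-value lfdr plus the fitted null (eta0, sigma0)."""

    def __init__(self, lfdr: np.ndarray, eta0: float, sigma0: float):
        self.lfdr = lfdr
        self.eta0 = eta0
        self.sigma0 = sigma0


def _null_scale(x: np.ndarray, central_quantile: float) -> tuple[float, float]:
    """Iteratively refitted truncation cutoff and half-normal scale.

    The first cutoff (a quantile of |delta|) can sit inside the signal when
    non-null pairs are plentiful, inflating the scale; refitting the cutoff
    as the corresponding quantile of the fitted null shrinks it back onto
    the null-dominated centre (central-matching style fixed point).
    """
    cutoff = float(np.quantile(x, central_quantile))
    if cutoff <= 0:
        cutoff = float(np.max(x)) * 0.5 or 1.0
    floor = float(np.quantile(x, 0.25))
    sigma0 = fit_halfnormal_null(x, cutoff)
    for _ in range(20):
        new_cutoff = max(
            sigma0 * float(stats.norm.ppf(0.5 + central_quantile / 2.0)), floor
        )
        if abs(new_cutoff - cutoff) < 1e-4 * max(cutoff, 1e-12):
            break
        cutoff = new_cutoff
        sigma0 = fit_halfnormal_null(x, cutoff)
    return cutoff, sigma0


def _lfdr_from_deltas(deltas: np.ndarray, central_quantile: float) -> LfdrFit:
    x = np.abs(deltas)
    cutoff, sigma0 = _null_scale(x, central_quantile)
    null_mass = 2.0 * stats.norm.cdf(cutoff / sigma0) - 1.0
    eta0 = min(1.0, float(np.mean(x <= cutoff)) / max(null_mass, 1e-12))
    f = grenander_density(x)
    f0 = 2.0 * stats.norm.pdf(x / sigma0) / sigma0
    raw = np.clip(eta0 * f0 / np.maximum(f, 1e-300), 0.0, 1.0)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    lfdr = iso.fit_transform(x, raw)
    return LfdrFit(np.clip(lfdr, 0.0, 1.0), eta0, sigma0)


def _lfdr_from_pvalues(pvalues: np.ndarray) -> LfdrFit:
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    f = grenander_density(p)  # decreasing density on [0, 1], uniform null f0 = 1
    eta0 = min(1.0, float(grenander_density(p, eval_at=np.array([np.max(p)]))[0]))
    raw = np.clip(eta0 / np.maximum(f, 1e-300), 0.0, 1.0)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    lfdr = iso.fit_transform(p, raw)  # non-decreasing in p == non-increasing in |delta|
    return LfdrFit(np.clip(lfdr, 0.0, 1.0), eta0, float("nan"))


def local_fdr(
    values: np.ndarray,
    input_mode: str = "delta",
    central_quantile: float = 0.75,
) -> LfdrFit:
    """Local FDR of differential-correlation statistics.

    Parameters
    ----------
    values:
        The delta statistics (``input_mode="delta"``, default) or two-sided
        p-values (``input_mode="pvalue"``).
    central_quantile:
        Quantile of |delta| below which the half-normal null is fitted;
        0.75 keeps the fit inside the null-dominated centre.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite statistic values")
    if np.unique(values).size == 1:
        raise ValueError("degenerate statistic distribution: all values identical")
    if values.size < _MIN_RECOMMENDED:
        warnings.warn(
            f"only {values.size} values; lfdr estimates are unreliable below "
            f"{_MIN_RECOMMENDED}",
            stacklevel=2,
        )
    if input_mode == "delta":
        return _lfdr_from_deltas(values, central_quantile)
    if input_mode == "pvalue":
        return _lfdr_from_pvalues(values)
    raise ValueError(f"unknown input_mode {input_mode!r}")
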