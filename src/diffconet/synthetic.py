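"""Synthetic two-condition expression data with planted differential-correlation modules.

The generator emulates a two-cell-line, EGF-treated time-course design
(2 replicates x 3 time points per condition, i.e. n = 6 samples each) in
which designated blocks of genes share a latent factor at a chosen
within-module correlation that may differ between the resistant ("R") and
sensitive ("S") condition.  Because every module is a single-factor
Gaussian block, the expected pairwise within-module Pearson correlation is
exactly the chosen rho, which gives analytically known ground truth for
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_expression_pair",
    "generate_null_pair",
    "generate_count_matrix",
]


def gene_names(n_genes: int) -> list[str]:
    """Stable gene identifiers G0001, G0002, ..."""
    width = max(4, len(str(n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(n_genes)]


def sample_names(condition: str, n_samples: int) -> list[str]:
    """Sample identifiers like R_t1_a: time point index and replicate letter."""
    names = []
    for i in range(n_samples):
        t, rep = divmod(i, 2)
        names.append(f"{condition}_t{t + 1}_{'ab'[rep]}")
    return names


@dataclass
class SyntheticSpec:
    """Full parameterisation of the planted-module generator.

    Parameters
    ----------
    n_genes:
        Total number of genes; genes not covered by ``module_sizes`` are
        independent background noise (module label 0).
    module_sizes:
        Sizes of the planted correlation modules (sum must not exceed
        ``n_genes``).
    rho_R, rho_S:
        Per-module within-module correlation in each condition, each in
        [0, 1).  A module is differential iff the two values differ.
    n_samples_R, n_samples_S:
        Samples per condition (default 6: 2 replicates x 3 time points).
    baseline_mean, noise_sd:
        Location/scale of the generated values; a vst-like scale (mean 8,
        sd 1) so fixtures look like normalised expression.  Pearson
        correlation is scale-free, so these do not affect the statistics.
    hub_rho:
        Optional per-module hub correlation.  When set, the first gene of
        each module carries factor loading sqrt(hub_rho) instead of
        sqrt(rho), planting a distinguished hub gene; None (default)
        leaves all module genes exchangeable.
    """

    n_genes: int
    module_sizes: list[int] = field(default_factory=list)
    rho_R: list[float] = field(default_factory=list)
    rho_S: list[float] = field(default_factory=list)
    n_samples_R: int = 6
    n_samples_S: int = 6
    baseline_mean: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0
    hub_rho: list[float] | None = None

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if any(m < 1 for m in self.module_sizes):
            raise ValueError(f"module_sizes must be positive, got {self.module_sizes}")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if not (len(self.rho_R) == len(self.rho_S) == len(self.module_sizes)):
            raise ValueError(
                "rho_R, rho_S and module_sizes must have equal length: "
                f"{len(self.rho_R)}, {len(self.rho_S)}, {len(self.module_sizes)}"
            )
        for name, rhos in (("rho_R", self.rho_R), ("rho_S", self.rho_S)):
            if any(not (0.0 <= r < 1.0) for r in rhos):
                raise ValueError(f"{name} entries must lie in [0, 1), got {rhos}")
        if self.hub_rho is not None:
            if len(self.hub_rho) != len(self.module_sizes):
                raise ValueError("hub_rho must match module_sizes in length")
            if any(not (0.0 <= r < 1.0) for r in self.hub_rho):
                raise ValueError(f"hub_rho entries must lie in [0, 1), got {self.hub_rho}")
        for name, n in (("n_samples_R", self.n_samples_R), ("n_samples_S", self.n_samples_S)):
            if n < 2:
                raise ValueError(f"{name} must be >= 2, got {n}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")


@dataclass
class GroundTruth:
    """Truth channel for recovery tests: module labels and differential flags."""

    labels: pd.Series  # gene -> module label, 0 = background
    differential: dict[int, bool]  # module label -> rho_R != rho_S
    hub_genes: dict[int, str] = field(default_factory=dict)  # module -> planted hub

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValueError("ground-truth labels must cover each gene exactly once")


def _simulate_condition(
    spec: SyntheticSpec, rhos: list[float], n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Single-factor Gaussian blocks: x_g = mu + sd*(sqrt(rho)*f_m + sqrt(1-rho)*eps_g)."""
    x = np.empty((spec.n_genes, n_samples))
    pos = 0
    for m, (size, rho) in enumerate(zip(spec.module_sizes, rhos)):
        f = rng.standard_normal(n_samples)
        eps = rng.standard_normal((size, n_samples))
        loadings = np.full(size, math.sqrt(rho))
        if spec.hub_rho is not None:
            loadings[0] = math.sqrt(spec.hub_rho[m])
        x[pos : pos + size] = (
            loadings[:, None] * f[None, :]
            + np.sqrt(1.0 - loadings[:, None] ** 2) * eps
        )
        pos += size
    n_bg = spec.n_genes - pos
    if n_bg:
        x[pos:] = rng.standard_normal((n_bg, n_samples))
    return spec.baseline_mean + spec.noise_sd * x


def generate_expression_pair(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (R, S) expression matrices plus ground truth.

    Within module m the expected pairwise correlation in condition c is
    rho_c[m]; background genes are independent noise.  Identical spec +
    seed gives bit-identical output.
    """
    spec.validate()
    genes = gene_names(spec.n_genes)
    ss = np.random.SeedSequence(spec.seed)
    rng_r, rng_s = (np.random.default_rng(s) for s in ss.spawn(2))

    mat_r = _simulate_condition(spec, spec.rho_R, spec.n_samples_R, rng_r)
    mat_s = _simulate_condition(spec, spec.rho_S, spec.n_samples_S, rng_s)
    expr_r = pd.DataFrame(mat_r, index=genes, columns=sample_names("R", spec.n_samples_R))
    expr_s = pd.DataFrame(mat_s, index=genes, columns=sample_names("S", spec.n_samples_S))
    expr_r.index.name = expr_s.index.name = "gene"

    labels = np.zeros(spec.n_genes, dtype=int)
    differential: dict[int, bool] = {}
    hub_genes: dict[int, str] = {}
    pos = 0
    for m, size in enumerate(spec.module_sizes, start=1):
        labels[pos : pos + size] = m
        differential[m] = spec.rho_R[m - 1] != spec.rho_S[m - 1]
        if spec.hub_rho is not None:
            hub_genes[m] = genes[pos]
        pos += size
    truth = GroundTruth(
        labels=pd.Series(labels, index=genes, name="module"),
        differential=differential,
        hub_genes=hub_genes,
    )
    return expr_r, expr_s, truth


def generate_null_pair(
    n_genes: int, n_samples: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two same-distribution independent-gene matrices: no differential signal.

    Used for calibrating the local-FDR machinery; requires n_samples >= 4
    because the differential statistic's variance term 1/(n-3) is undefined
    otherwise.
    """
    if n_genes < 2:
        raise ValueError(f"n_genes must be >= 2, got {n_genes}")
    if n_samples <= 3:
        raise ValueError(
            f"n_samples must exceed 3 (delta denominator 1/(n-3)), got {n_samples}"
        )
    spec = SyntheticSpec(
        n_genes=n_genes,
        n_samples_R=n_samples,
        n_samples_S=n_samples,
        seed=seed,
    )
    expr_r, expr_s, _ = generate_expression_pair(spec)
    return expr_r, expr_s


def generate_count_matrix(
    n_genes: int,
    n_samples: int,
    zero_fraction_targets: list[float] | None = None,
    seed: int = 0,
    mean_count: float = 50.0,
) -> pd.DataFrame:
    """Non-negative integer count matrix with controllable per-gene zero fractions.

    ``zero_fraction_targets`` is cycled over genes; gene i has exactly
    ``round(target * n_samples)`` zero entries (positions chosen at random),
    so retention under a "count >= 1 in at least half the samples" filter is
    deterministic per gene: target 1.0 forces removal, 0.0 forces retention.
    """
    if n_genes < 1 or n_samples < 1:
        raise ValueError(f"dimensions must be positive, got {n_genes} x {n_samples}")
    targets = zero_fraction_targets or [0.0]
    if any(not (0.0 <= t <= 1.0) for t in targets):
        raise ValueError(f"zero_fraction_targets must lie in [0, 1], got {targets}")
    rng = np.random.default_rng(seed)
    counts = 1 + rng.poisson(mean_count - 1, size=(n_genes, n_samples))
    for i in range(n_genes):
        n_zero = round(targets[i % len(targets)] * n_samples)
        if n_zero:
            zero_at = rng.choice(n_samples, size=n_zero, replace=False)
            counts[i, zero_at] = 0
    df = pd.DataFrame(
        counts,
        index=gene_names(n_genes),
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )
    df.index.name = "gene"
    return df
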