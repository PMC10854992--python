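import numpy as np
import pandas as pd
import pytest

from diffconet.synthetic import SyntheticSpec, generate_expression_pair


@pytest.fixture
def planted_pair():
    """3 differential modules of 40 genes, no background, n = 50 per condition."""
    spec = SyntheticSpec(
        n_genes=120,
        module_sizes=[40, 40, 40],
        rho_R=[0.8, 0.8, 0.8],
        rho_S=[0.0, 0.0, 0.0],
        n_samples_R=50,
        n_samples_S=50,
        seed=11,
    )
    expr_r, expr_s, truth = generate_expression_pair(spec)
    return expr_r, expr_s, truth


@pytest.fixture
def small_expr():
    """Deterministic 5-gene x 6-sample matrix for exact-formula oracles."""
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(5)]
    return pd.DataFrame(
        rng.normal(8, 1, size=(5, 6)),
        index=genes,
        columns=[f"R_t{t}_{r}" for t in (1, 2, 3) for r in "ab"],
    )
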