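import numpy as np
import pandas as pd
import pytest

from bloodewas.datamodel import BetaMatrix, SampleMeta
from bloodewas.simulate import SimConfig, generate_cohort

# A deliberately small synthetic cohort shared across test modules.
TINY = SimConfig(
    n_cases=40, n_controls=80, n_cpgs=200,
    n_signature_cpgs_per_type=10,
    cell_effect_counts={"B": 2, "Mono": 1, "CD4T": 0, "CD8T": 0, "NK": 0, "Neu": 0},
    n_direct_cpgs=4, n_direct_qtl_cpgs=1, n_methqtl_cpgs=3,
    n_prs_snps=20, n_background_snps=10,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(TINY)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def simple_meta():
    """12-sample metadata with constant covariates (reduce to intercept-only)."""
    n = 12
    return SampleMeta(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "phenotype": [1] * 6 + [0] * 6,
        "age": [40.0] * n,
        "sex": ["F"] * n,
        "region": ["r"] * n,
    }))


def make_beta(values, prefix_cpg="cg", prefix_s="s"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return BetaMatrix(
        values,
        np.array([f"{prefix_cpg}{i}" for i in range(values.shape[0])], dtype=object),
        np.array([f"{prefix_s}{j}" for j in range(values.shape[1])], dtype=object),
    )
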