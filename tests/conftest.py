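import numpy as np
import pandas as pd
import pytest

from suvarness.io import ExpressionMatrix
from suvarness.simulate import CohortConfig


def random_matrix(rng, n_genes=10, n_samples=6, prefix="g"):
    values = rng.normal(5.0, 1.0, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [5.0, 5.0, 8.0]],
            index=["ga", "gb", "gc"],
            columns=["s1", "s2", "s3"],
        )
    )


@pytest.fixture
def two_group_cohort():
    """Well-separated two-group synthetic cohort for classifier tests."""
    from suvarness.simulate import generate_cohort

    cfg = CohortConfig(
        n_genes=100,
        n_samples_per_group={"A": 20, "B": 20},
        n_signature_genes=20,
        effect_size=3.0,
        seed=7,
    )
    return generate_cohort(cfg)
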