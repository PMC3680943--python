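import numpy as np
import pandas as pd
import pytest

from vasculotype import ExpressionMatrix, SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (seed 1): (matrix, samples, truth)."""
    return generate_cohort(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def tumor_view(default_cohort):
    """Tumor-only matrix plus the tumor annotation indexed by sample id."""
    matrix, samples, truth = default_cohort
    tumor = samples[samples["tissue"] == "tumor_vasculature"].set_index("sample_id")
    return matrix.subset_samples(list(tumor.index)), tumor, truth


@pytest.fixture
def small_matrix():
    values = np.array(
        [
            [1.0, 2.0, 3.0],
            [4.0, 6.0, 5.0],
            [7.0, 7.0, 7.0],
        ]
    )
    return ExpressionMatrix(values, ("g1", "g2", "g3"), ("s1", "s2", "s3"))


def make_matrix(values, gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        tuple(f"{gene_prefix}{i}" for i in range(values.shape[0])),
        tuple(f"{sample_prefix}{j}" for j in range(values.shape[1])),
    )
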