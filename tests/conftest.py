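from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from reosig import ExpressionMatrix, SyntheticCohortConfig, generate_cohort

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def tcell_gmt_path() -> Path:
    return DATA_DIR / "tcell_sets_synthetic.gmt"


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with a hand-checkable ordering structure.

    gA > gB in 4/4 samples; gA > gC in 3/4; gB > gC in 2/4.
    """
    values = pd.DataFrame(
        {
            "s1": [9.0, 5.0, 1.0],
            "s2": [8.0, 4.0, 2.0],
            "s3": [7.0, 3.0, 7.5],
            "s4": [6.0, 2.0, 3.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def planted_cohort():
    """One planted reversed pair at stability 0.95/0.95 among 200 background genes."""
    config = SyntheticCohortConfig(
        n_genes=202,
        n_samples_per_class=(100, 100),
        planted_reversed_pairs=[(0, 1, 0.95, 0.95)],
        rng_seed=1,
    )
    return generate_cohort(config)


def random_matrix(rng: np.random.Generator, n_genes: int, n_samples: int,
                  tie_prob: float = 0.3, missing_prob: float = 0.1) -> ExpressionMatrix:
    """Small random matrix with deliberate ties and missing values."""
    values = rng.integers(1, 6, size=(n_genes, n_samples)).astype(float)  # ties likely
    keep_continuous = rng.random((n_genes, n_samples)) > tie_prob
    values = np.where(keep_continuous, values + rng.random((n_genes, n_samples)), values)
    values[rng.random((n_genes, n_samples)) < missing_prob] = np.nan
    frame = pd.DataFrame(
        values,
        index=[f"g{i:02d}" for i in range(n_genes)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(frame)
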