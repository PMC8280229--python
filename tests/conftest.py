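import numpy as np
import pandas as pd
import pytest

from metacms.core_io import ExpressionMatrix, MarkerGeneList
from metacms.synthetic import SyntheticConfig, generate, generate_reference_panel


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(0)
    return ExpressionMatrix(
        [f"g{i}" for i in range(10)],
        [f"s{j}" for j in range(6)],
        rng.normal(6.0, 1.0, (10, 6)),
    )


@pytest.fixture
def two_sample_one_marker():
    """Hand-checkable background-score instance: one marker gene, values (1, 3)."""
    x = ExpressionMatrix(
        ["marker", "other"],
        ["s1", "s2"],
        np.array([[1.0, 3.0], [5.0, 5.0]]),
    )
    return x, MarkerGeneList(["marker"])


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=42)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate(default_config)


@pytest.fixture(scope="session")
def reference_panel(default_config):
    return generate_reference_panel(default_config)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for tests that retrain models repeatedly."""
    cfg = SyntheticConfig(
        seed=7,
        n_genes=400,
        block_size=20,
        n_hepatocyte_markers=20,
        n_primaries_per_class=12,
        n_metastases=40,
        n_normal_liver=6,
        n_reference_per_class=8,
    )
    return generate(cfg)


def labels_of(cohort, matrix) -> pd.Series:
    return cohort.true_labels().loc[list(matrix.sample_ids)]
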