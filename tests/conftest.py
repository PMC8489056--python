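import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import refstab as rs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def three_gene_matrix() -> rs.CqMatrix:
    """A (A parallel to B, C wobbling) matrix with hand-computable scores."""
    values = pd.DataFrame(
        {
            "s1": [20.0, 25.0, 20.0],
            "s2": [21.0, 26.0, 22.0],
            "s3": [22.0, 27.0, 21.0],
        },
        index=["A", "B", "C"],
    )
    return rs.CqMatrix(values=values)


@pytest.fixture
def study_dataset() -> rs.CqDataset:
    """One draw of the study-shaped design (7 genes x 8 groups x 3 x 3)."""
    return rs.generate_cq_dataset(rs.default_config(seed=42))


@pytest.fixture
def study_matrix(study_dataset) -> rs.CqMatrix:
    return rs.collapse_replicates(study_dataset.records, meta=study_dataset.meta)


def random_cq_matrix(rng: np.random.Generator, n_genes=5, n_samples=8) -> rs.CqMatrix:
    """Unstructured random Cq matrix for oracle comparisons."""
    values = pd.DataFrame(
        rng.uniform(15.0, 30.0, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return rs.CqMatrix(values=values)
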