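import numpy as np
import pandas as pd
import pytest

from thanatoset.panel import BulkExpression


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_bulk(values: np.ndarray, groups: list[str], timepoints: list[str] | None = None,
              model: str = "m", age: str = "adult", genes: list[str] | None = None) -> BulkExpression:
    """Small BulkExpression factory for hand-crafted matrices."""
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i:03d}" for i in range(1, n_genes + 1)]
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "group": groups,
            "timepoint": timepoints or ["sham"] * n_samples,
            "model": model,
            "age": age,
        },
        index=samples,
    )
    return BulkExpression(
        values=pd.DataFrame(values, index=genes, columns=samples), sample_meta=meta
    )


@pytest.fixture
def bulk_factory():
    return make_bulk
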