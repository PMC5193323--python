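import numpy as np
import pandas as pd
import pytest

from taudiv import ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 6 tissues, linear scale: a testis-specific gene, a
    ubiquitous gene and an intermediate one."""
    data = pd.DataFrame(
        {
            "brain": [0.2, 8.0, 8.0],
            "cerebellum": [0.1, 8.0, 2.0],
            "heart": [0.0, 8.0, 2.0],
            "kidney": [0.5, 8.0, 2.0],
            "liver": [0.3, 8.0, 2.0],
            "testis": [64.0, 8.0, 2.0],
        },
        index=["g_testis", "g_ubiq", "g_mid"],
    )
    data.index.name = "gene_id"
    return ExpressionMatrix("human", "toy", data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
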