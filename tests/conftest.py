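import numpy as np
import pandas as pd
import pytest

from preactivation import ExpressionMatrix, GeneSet


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with simple values and genotype metadata."""
    values = pd.DataFrame(
        {
            "s1": [2.0, 5.0, 1.0],
            "s2": [4.0, 5.0, 1.0],
            "s3": [6.0, 5.0, 3.5],
            "s4": [8.0, 5.0, 3.5],
        },
        index=["g1", "g2", "g3"],
    )
    meta = pd.DataFrame(
        {"genotype": ["a", "a", "b", "b"]}, index=["s1", "s2", "s3", "s4"]
    )
    return ExpressionMatrix(values, meta)


@pytest.fixture
def universe10() -> GeneSet:
    return GeneSet("universe", frozenset(f"g{i}" for i in range(10)))
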