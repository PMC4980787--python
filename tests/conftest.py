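import numpy as np
import pytest

from mabc.datasets import ExpressionDataset


@pytest.fixture
def toy_dataset():
    """4 samples x 3 genes, two classes; gene g1 separates the classes."""
    return ExpressionDataset(
        values=np.array(
            [
                [1.0, 0.1, 5.0],
                [2.0, 0.2, 5.0],
                [3.0, 0.9, 5.0],
                [4.0, 1.0, 5.0],
            ]
        ),
        labels=["A", "A", "B", "B"],
        gene_ids=["g0", "g1", "g2"],
    )


@pytest.fixture
def separable_dataset():
    """10 samples x 4 genes; gene 0 splits the classes by a wide margin."""
    rng = np.random.default_rng(42)
    values = rng.normal(0.0, 0.05, size=(10, 4))
    labels = np.array([0] * 5 + [1] * 5)
    values[labels == 1, 0] += 1.0
    return ExpressionDataset(values=values, labels=labels)
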