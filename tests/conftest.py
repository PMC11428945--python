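import warnings

import numpy as np
import pandas as pd
import pytest

from gutnet.data_io import CountTable, SampleMetadata
from gutnet.network import CorrelationNetwork

warnings.filterwarnings("ignore", message="SparCC on fewer than 10 samples")


@pytest.fixture
def small_table() -> CountTable:
    counts = np.array([[5, 3, 0, 2],
                       [1, 0, 4, 5],
                       [2, 2, 2, 2]])
    return CountTable(["s1", "s2", "s3"], ["t1", "t2", "t3", "t4"], counts)


@pytest.fixture
def small_metadata() -> SampleMetadata:
    frame = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "group": ["control", "stress", "control"],
        "sex": ["female", "castrated_male", "female"],
        "pen": ["p1", "p2", "p1"],
        "timepoint": ["t1", "t1", "t1"],
    })
    return SampleMetadata(frame)


def random_network(rng: np.random.Generator, n: int = 20) -> CorrelationNetwork:
    """Random symmetric correlation-like adjacency with unit diagonal."""
    a = rng.uniform(-1, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return CorrelationNetwork([f"n{i}" for i in range(n)], a)
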