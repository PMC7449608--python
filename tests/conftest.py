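import numpy as np
import pandas as pd
import pytest

from ecoassembly.data import CountTable, StudyDesign


@pytest.fixture
def tiny_table():
    return CountTable(["f1", "f2"], ["s1", "s2"], np.array([[3, 0], [1, 2]]))


@pytest.fixture
def two_group_design():
    return StudyDesign(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "reactor": ["R1", "R2", "R1", "R2"],
                "level": ["L", "L", "H", "H"],
                "day": [1, 1, 1, 1],
            }
        )
    )


def random_count_table(rng, n_features=None, n_samples=None, max_count=50):
    """Random integer table with every sample nonempty."""
    f = n_features or rng.integers(2, 10)
    s = n_samples or rng.integers(2, 6)
    counts = rng.integers(0, max_count, size=(f, s))
    for j in range(s):
        if counts[:, j].sum() == 0:
            counts[rng.integers(0, f), j] = 1
    return CountTable(
        [f"f{i:03d}" for i in range(f)], [f"s{j:02d}" for j in range(s)], counts
    )
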