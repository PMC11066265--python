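import numpy as np
import pytest
from skbio import TreeNode

import estasm


@pytest.fixture
def toy_table():
    """4 samples x 4 taxa, small integers."""
    counts = np.array([
        [10, 0, 3, 1],
        [8, 2, 0, 0],
        [0, 5, 5, 2],
        [1, 1, 1, 1],
    ])
    return estasm.CountTable(["S1", "S2", "S3", "S4"],
                             ["A", "B", "C", "D"], counts)


@pytest.fixture
def toy_tree():
    return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])


@pytest.fixture(scope="session")
def bundle():
    """Session-wide simulated dataset on the default gradient."""
    cfg = estasm.SimConfig(n_taxa=80, n_samples=24, depth=1000, seed=7)
    return estasm.simulate_dataset(cfg)
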