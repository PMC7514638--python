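import numpy as np
import pytest

from ardne.data import table1_fixture
from ardne.system import NeighborhoodDecisionSystem


@pytest.fixture
def table1():
    return table1_fixture()


def random_system(seed, max_n=8, max_m=5, n_classes=2):
    """Small random decision table on [0,1] values with a random radius."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_n + 1))
    m = int(rng.integers(1, max_m + 1))
    values = rng.random((n, m))
    labels = rng.integers(0, n_classes, size=n)
    labels[0] = 0  # guarantee at least one sample in class 0
    # radius commensurate with the data's own distance scale: a low
    # quantile of the pairwise full-set distances, so neighborhoods are
    # informative rather than uniformly impure
    diffs = values[:, None, :] - values[None, :, :]
    dists = np.sqrt((diffs**2).sum(-1))[np.triu_indices(n, 1)]
    q = float(rng.uniform(0.1, 0.4))
    delta = float(np.clip(np.quantile(dists, q), 0.01, 1.0))
    return NeighborhoodDecisionSystem(
        values=values, decisions=labels.astype(str), delta=delta
    )
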