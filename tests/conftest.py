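import numpy as np
import pytest

from cyclenet import SnapshotSequence, toy_fixture


@pytest.fixture
def toy():
    """Five nodes, three unit windows, two two-window triangles."""
    return toy_fixture()


def random_snapshots(rng, n_max=10, t_max=5, p=0.25) -> SnapshotSequence:
    """Small random snapshot sequence: per-window Erdős–Rényi edges."""
    n = int(rng.integers(4, n_max + 1))
    T = int(rng.integers(2, t_max + 1))
    nodes = tuple(range(n))
    windows = []
    for _ in range(T):
        edges = set()
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    edges.add((i, j))
        windows.append(frozenset(edges))
    return SnapshotSequence(nodes=nodes, edges=tuple(windows), delta_t=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
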