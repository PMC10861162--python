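import numpy as np
import pytest

from nbssni.cohort import Cohort, Subject


def random_symmetric(rng, n, density=0.6, low=0.5, high=2.0, connected=True):
    """Random weighted symmetric adjacency with zero diagonal.

    Retries until connected when requested (small n only).
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    for _ in range(200):
        mask = np.triu(rng.random((n, n)) < density, k=1)
        w = np.triu(rng.uniform(low, high, (n, n)), k=1) * mask
        a = w + w.T
        if not connected:
            return a
        ncomp, _ = connected_components(csr_matrix(a != 0), directed=False)
        if ncomp == 1:
            return a
    raise RuntimeError("failed to draw a connected graph")


def make_cohort(rng, n=6, n1=3, n2=3, planted=None, cnr=0.0, sigma=1.0):
    """Small cohort with random sparse structural nets and Gaussian
    functional nets; ``planted`` edges get +cnr in group 1."""
    iu, ju = np.triu_indices(n, k=1)
    planted = set(planted or [])

    def functional(boost):
        vals = rng.normal(0, sigma, iu.size)
        if boost:
            for u, v in planted:
                vals[u * (2 * n - u - 1) // 2 + (v - u - 1)] += cnr
        a = np.zeros((n, n))
        a[iu, ju] = vals
        return a + a.T

    g1 = [
        Subject(id=f"a{i}", structural=random_symmetric(rng, n),
                functional=functional(True))
        for i in range(n1)
    ]
    g2 = [
        Subject(id=f"b{i}", structural=random_symmetric(rng, n),
                functional=functional(False))
        for i in range(n2)
    ]
    return Cohort(group1=g1, group2=g2, node_ids=[f"n{i}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
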