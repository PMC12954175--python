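import numpy as np
import pytest

from spacebf import build_mst, grid_coords


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_coords():
    """20-location jittered grid."""
    return grid_coords(20, seed=42)


@pytest.fixture
def small_mst(small_coords):
    return build_mst(small_coords, jitter_scale=0.01, seed=42)


def spanning_trees(n, edges):
    """Brute-force enumeration of all spanning trees of a small graph."""
    import itertools

    trees = []
    for combo in itertools.combinations(range(len(edges)), n - 1):
        sub = [edges[i] for i in combo]
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ok = True
        for u, v in sub:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok and len({find(i) for i in range(n)}) == 1:
            trees.append(frozenset(map(tuple, sub)))
    return trees
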