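import dataclasses

import numpy as np
import pytest

import manifoldseg as ms


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def fast_spec():
    """Small phantom spec for quick pipeline tests (128^2, fewer lesions)."""
    return ms.PhantomSpec(shape=(128, 128), n_lesions=5, seed=7)


@pytest.fixture(scope="session")
def fast_phantom(fast_spec):
    return ms.make_phantom(fast_spec)


@pytest.fixture(scope="session")
def fast_config():
    return ms.RunConfig(resolution=None, seed=3)


@pytest.fixture
def tiny_volume(rng):
    """4-channel 8x8 volume with a T1post channel and full brain mask."""
    channels = {name: rng.normal(50, 5, size=(8, 8))
                for name in ("PD", "T2W", "FLAIR", "T1pre")}
    channels["T1post"] = channels["T1pre"].copy()
    return ms.MultiparametricVolume(channels=channels,
                                    brain_mask=np.ones((8, 8), dtype=bool))


def make_random_graph(rng, n, extra_edges=2):
    """Random connected weighted graph: a spanning chain plus extras."""
    import scipy.sparse as sp

    rows, cols, vals = [], [], []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        rows.append(i), cols.append(j)
        vals.append(float(rng.uniform(0.1, 2.0)))
    for _ in range(extra_edges * n):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            rows.append(int(i)), cols.append(int(j))
            vals.append(float(rng.uniform(0.1, 2.0)))
    a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    a = a.maximum(a.T)
    return ms.NeighborGraph(adjacency=a, k=1)
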