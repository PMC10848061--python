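import numpy as np
import pytest

from sdconnectome import Connectome


def random_connectome(rng: np.random.Generator, n: int, density: float = 0.5,
                      integer: bool = True, max_weight: int = 50) -> Connectome:
    """Random valid weighted undirected network (possibly disconnected)."""
    iu, ju = np.triu_indices(n, 1)
    present = rng.random(iu.size) < density
    if integer:
        vals = rng.integers(1, max_weight + 1, size=iu.size).astype(float)
    else:
        vals = rng.uniform(0.1, float(max_weight), size=iu.size)
    w = np.zeros((n, n))
    w[iu[present], ju[present]] = vals[present]
    w += w.T
    return Connectome(w)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def triangle_135():
    """Triangle with weights w01=1, w02=2, w12=3: strengths (3, 4, 5)."""
    w = np.array([[0.0, 1, 2], [1, 0, 3], [2, 3, 0]])
    return Connectome(w)


@pytest.fixture
def path3():
    """3-node path 0-1-2 with unit weights."""
    w = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return Connectome(w)
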