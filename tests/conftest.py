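import numpy as np
import pytest

from tractnet.phantoms import Bundle, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def straight_bundle_phantom():
    """One straight bundle along x with two endpoint ROIs, noiseless."""
    spec = PhantomSpec(
        grid_shape=(25, 8, 6),
        bundles=[
            Bundle(path=np.array([[2.0, 3.0, 4.0], [22.0, 3.0, 4.0]]), radius=1.2, label=1)
        ],
    )
    return spec, make_phantom(spec)


@pytest.fixture(scope="session")
def isotropic_phantom():
    spec = PhantomSpec(grid_shape=(4, 4, 4), bundles=[])
    return spec, make_phantom(spec)


def random_adjacency(n, p, rng):
    """Random undirected adjacency matrix without self-loops."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1)
    return adj | adj.T
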