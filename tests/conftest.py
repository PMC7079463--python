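import numpy as np
import pytest

from spikeseg.architecture import build_network, gmrnet_spec, lpnet_spec
from spikeseg.benchmark import run_small_benchmark


@pytest.fixture(scope="session")
def small_run():
    """One full scaled-down study: generate plants, train both stages,
    evaluate held-out segmentation and counting.  Shared across tests
    because it is by far the most expensive fixture."""
    return run_small_benchmark(seed=7)


@pytest.fixture(scope="session")
def tiny_nets():
    """Untrained micro-scale networks (32-px patches, widths 2/3/4) for
    fast plumbing tests."""
    lpnet = build_network(lpnet_spec((2, 3, 4), 32, 3), seed=0)
    gmrnet = build_network(gmrnet_spec((2, 3, 4), 32, 1), seed=0)
    return lpnet, gmrnet


@pytest.fixture
def rng():
    return np.random.default_rng(0)
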