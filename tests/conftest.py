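import numpy as np
import pytest

from strandcv.architecture import StrandGeometry, generate_architecture
from strandcv.solver import CouplingScheme, build_network, simulate_propagation

# Reduced strand used by most solver tests: same node spacing and cell
# statistics as the full 3000x150 um strand, shorter and narrower.
SMALL_GEO = StrandGeometry(length=1000.0, width=60.0, node_spacing=5.0)
# Near the full-size calibrated reference coupling; exact control CV is not
# required for the small-strand property tests.
G_REF_SMALL = 0.05


@pytest.fixture(scope="session")
def small_geometry():
    return SMALL_GEO


@pytest.fixture(scope="session")
def small_arch():
    return generate_architecture(SMALL_GEO, seed=7)


@pytest.fixture(scope="session")
def small_pcm_run(small_arch):
    """One propagated beat on a small all-PCM strand (shared, read-only)."""
    net = build_network(small_arch, CouplingScheme.baseline(G_REF_SMALL))
    return simulate_propagation(net)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
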