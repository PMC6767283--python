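import numpy as np
import pytest
from threadpoolctl import threadpool_limits

from irivsca import make_fixture

# single-threaded BLAS: bit-reproducible reductions regardless of host CPUs
# (and faster for the many small matmuls in the IRIV inner loop)
threadpool_limits(limits=1)


@pytest.fixture(scope="session")
def lab_small():
    """Pinned 63×200 synthetic laboratory fixture with 5 planted bands."""
    ss, truth = make_fixture("lab-small")
    return ss, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
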