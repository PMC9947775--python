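import os

# keep BLAS single-threaded: deterministic timings and no oversubscription
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import numpy as np
import pytest

from hcnet.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 32-cube phantom pair shared by I/O and pipeline tests."""
    return generate_phantom(PhantomSpec(grid_size=32, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
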