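import logging

import numpy as np
import pytest

from prunet.nn import set_default_dtype

logging.getLogger("prunet").setLevel(logging.ERROR)


@pytest.fixture
def float64_mode():
    """Run a test in float64 (for oracle and finite-difference comparisons)."""
    set_default_dtype(np.float64)
    yield
    set_default_dtype(np.float32)


@pytest.fixture(scope="session")
def tiny_skin_samples():
    from prunet.data import generate_dataset
    return generate_dataset("skin_like", 12, 32, seed=101)


@pytest.fixture(scope="session")
def small_widths():
    return (8, 16, 32, 64, 128)
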