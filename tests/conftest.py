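import math

import numpy as np
import pytest

from cortexfield.fields_core import ConnectivityKernel, ScalarField2p1
from cortexfield.single_layer import kg_params


@pytest.fixture
def weak_kernel():
    """Weak-connectivity kernel used across the wave tests (U=0.1, R=1)."""
    return ConnectivityKernel.from_gain(0.1, 1.0)


@pytest.fixture
def weak_params(weak_kernel):
    return kg_params(weak_kernel)


@pytest.fixture
def smooth_field():
    """Smooth two-mode complex field on a 48x48 periodic grid, rotating in
    phase so it carries nonzero total charge."""
    nx = ny = 48
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    vals = (0.3 * np.exp(2j * math.pi * (2 * X / nx + Y / ny))
            + 0.1 * np.exp(2j * math.pi * (3 * Y / ny)))
    return ScalarField2p1(vals, 1.0, velocity=-1j * vals)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
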