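import numpy as np
import pytest

from bemamr import (
    DirectBackend,
    HeadModel,
    build_nearfield,
    make_icosphere,
)


@pytest.fixture(scope="session")
def backend():
    return DirectBackend()


@pytest.fixture(scope="session")
def numpy_backend():
    return DirectBackend(use_compiled=False)


@pytest.fixture(scope="session")
def sphere320():
    return make_icosphere(0.1, 2)


@pytest.fixture(scope="session")
def sphere1280():
    return make_icosphere(0.1, 3)


@pytest.fixture()
def single_shell_model(sphere320):
    from bemamr import TriSurface

    surf = TriSurface(sphere320.vertices.copy(), sphere320.facets.copy(), "shell")
    return HeadModel([surf], [0.275], [1.654])


@pytest.fixture()
def two_shell_model():
    """Two nested shells, 640 facets total: small enough for dense oracles."""
    inner = make_icosphere(0.07, 2)
    outer = make_icosphere(0.1, 2)
    return HeadModel([inner, outer], [0.33, 0.0042], [0.0042, 0.0])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
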