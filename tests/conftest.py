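import numpy as np
import pytest

from mvplnmix.model_core import ComponentParams, OffsetMatrix
from mvplnmix.simulate import build_benchmark_design, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def sim2_small():
    """One sim2-style dataset at reduced N, shared across tests."""
    design = build_benchmark_design("sim2", seed=1, scale=0.3)
    return simulate(design, rng=np.random.default_rng([1, 0, 2]))


@pytest.fixture(scope="session")
def sim1_small():
    design = build_benchmark_design("sim1", seed=1, scale=0.2)
    return simulate(design, rng=np.random.default_rng([1, 0, 1]))


@pytest.fixture
def scalar_component():
    return ComponentParams(M=[[0.2]], Phi=[[1.2]], Omega=[[0.9]])


@pytest.fixture
def unit_offsets():
    return OffsetMatrix([[1.0]])
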