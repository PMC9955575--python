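import numpy as np
import pytest

from bntissue.field import FieldParams, LatticeSpec


@pytest.fixture
def params() -> FieldParams:
    return FieldParams()


@pytest.fixture
def small_lattice() -> LatticeSpec:
    return LatticeSpec((6, 6, 6), 20.0)


@pytest.fixture
def tiny_lattice() -> LatticeSpec:
    return LatticeSpec((2, 1, 1), 20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(20230209))
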