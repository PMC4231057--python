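import numpy as np
import pytest

from bbbassay import AssayDesign, EffectModel, TrueKinetics


@pytest.fixture
def design() -> AssayDesign:
    return AssayDesign()


@pytest.fixture
def kinetics() -> TrueKinetics:
    return TrueKinetics()


@pytest.fixture
def effects() -> EffectModel:
    return EffectModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
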