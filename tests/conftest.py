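import numpy as np
import pytest

from biofilmarch import SyntheticStackSpec, generate_stack


@pytest.fixture(scope="session")
def compact_stack():
    spec = SyntheticStackSpec(architecture="compact", peak_coverage=0.5, seed=11)
    return generate_stack(spec)


@pytest.fixture(scope="session")
def porous_stack():
    spec = SyntheticStackSpec(architecture="porous", peak_coverage=0.5, seed=11)
    return generate_stack(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
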