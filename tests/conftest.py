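import numpy as np
import pytest

from bvquant.classify import classify_stack
from bvquant.synthetic import StackSpec, fixture_small, generate_stack


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_fixture():
    """Deterministic hand-built stack with its expected class map."""
    return fixture_small()


@pytest.fixture(scope="session")
def synthetic_field():
    """One mid-viability synthetic stack with nuclei, plus its class map."""
    spec = StackSpec(viable_fraction=0.5, thickness_um=10.0, n_epithelial=2)
    stack, truth = generate_stack(spec, seed=1234)
    return stack, truth, classify_stack(stack)
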