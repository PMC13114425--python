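import numpy as np
import pytest

from uasrd import load_builtin


@pytest.fixture(scope="session")
def tensile():
    """30 polyester-fiber tensile strengths (fractions of nominal maximum)."""
    return load_builtin("tensile-strength").values


@pytest.fixture(scope="session")
def p3():
    """21 normalised P3-algorithm computing times."""
    return load_builtin("p3-times").values


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
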